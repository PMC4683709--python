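"""End-to-end orchestration: gene models -> sites -> events -> statistics.

The anchor species (DDB by default) is the coordinate system: every other
species is aligned pairwise to its ortholog and intron positions are keyed by
``(anchor gene, anchor-CDS offset, phase)``. A presence/absence/unknown
profile per site then feeds Dollo parsimony; losses on the focal terminal
branches are characterised (precision, adjacency, repeats, position, GC) and
the mechanism statistics are computed.

Site states per species at a key:

* ``present`` — the species has an intron at that column and phase;
* ``absent``  — it aligns there with flank similarity above the quality
  threshold and has no intron;
* ``unknown`` — no ortholog, or the neighbourhood is unalignable; unknowns
  never force losses and block gain calls.

Sites where an extant intron at a discordant position lacks exact splice
junction support (when junction data are supplied) are discarded entirely,
mirroring the re-annotation step of the original analysis.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import genome_io, loss_features, orthology, parsimony, stats
from .gain_source import filter_source_hits, splice_boundary_check
from .genome_io import Intron
from .orthology import OrthologPair, column_to_offset, offset_to_column
from .parsimony import ABSENT, PRESENT, UNKNOWN, SpeciesTree

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    fasta: dict  # species -> path
    gff: dict
    hits: dict = field(default_factory=dict)  # "A_vs_B" or (A, B) -> path
    junctions: dict = field(default_factory=dict)  # species -> path (optional)
    gain_hits: dict = field(default_factory=dict)  # species -> path (optional)
    tree_newick: str = parsimony.DEFAULT_TREE_NEWICK
    anchor: str = "DDB"
    focal: tuple = ("DDB", "DPU")
    evalue_max: float = 1e-10
    identity_min: float = 25.0
    flank_window: int = 45
    min_similarity: float = 0.5
    junction_min_reads: int = 1
    precision_window: int = 15
    gc_window: int = 100
    repeat_k_max: int = 10
    resample_R: int = 10_000
    seed: int = 0
    run_id: str = ""
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.hits = {_pair_key(k): v for k, v in cfg.hits.items()}
        return cfg

    def validate(self) -> None:
        for name, mapping in (("fasta", self.fasta), ("gff", self.gff)):
            for sp, path in mapping.items():
                if not os.path.exists(path):
                    raise FileNotFoundError(f"{name} for {sp} not found: {path}")
        for key, path in self.hits.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"hit table {key} not found: {path}")


def _pair_key(k) -> tuple:
    if isinstance(k, str):
        a, _, b = k.partition("_vs_")
        return (a, b)
    return tuple(k)


def config_from_simulation(sim, resample_R: int = 10_000, outdir: str | None = None) -> RunConfig:
    """Build a :class:`RunConfig` straight from a ``SimulatedClade``."""
    return RunConfig(
        fasta=dict(sim.fasta),
        gff=dict(sim.gff),
        hits=dict(sim.rbh_hits),
        junctions=dict(sim.junctions),
        gain_hits=dict(sim.gain_hits),
        seed=sim.config.seed,
        resample_R=resample_R,
        run_id=sim.config.run_id,
        outdir=outdir,
    )


@dataclass
class _Site:
    """Working record for one projected intron position within a group."""

    gene: str  # anchor gene id
    offset: int  # anchor-CDS offset
    phase: int
    states: dict = field(default_factory=dict)  # species -> state
    introns: dict = field(default_factory=dict)  # species -> Intron
    offsets: dict = field(default_factory=dict)  # species -> own CDS offset
    discarded: str = ""
    ordinal: int = 0  # ancestral rank within the gene (non-gain sites)

    @property
    def site_id(self) -> str:
        return f"{self.gene}:{self.offset}:{self.phase}"


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("genome_io")
def _load_genomes(cfg: RunConfig):
    models, introns, rejects = {}, {}, {}
    for sp in cfg.fasta:
        genomes = genome_io.read_fasta(cfg.fasta[sp], species_id=sp)
        m, rej = genome_io.build_gene_models(cfg.gff[sp], genomes)
        models[sp] = {g.gene_id: g for g in m}
        introns[sp] = {g.gene_id: genome_io.extract_introns(g) for g in m}
        rejects[sp] = rej
        logger.info("%s: %d gene models (%d rejected)", sp, len(m), len(rej))
    return models, introns, rejects


@_stage("orthology")
def _ortholog_groups(cfg: RunConfig):
    groups: dict[str, dict[str, str]] = {}
    n_pairs = {}
    others = [sp for sp in cfg.fasta if sp != cfg.anchor]
    for other in others:
        fwd = orthology.read_blast_tab(cfg.hits[(cfg.anchor, other)])
        rev = orthology.read_blast_tab(cfg.hits[(other, cfg.anchor)])
        pairs = orthology.reciprocal_best_hits(fwd, rev, cfg.evalue_max, cfg.identity_min)
        n_pairs[f"{cfg.anchor}-{other}"] = len(pairs)
        for p in pairs:
            groups.setdefault(p.gene_a, {cfg.anchor: p.gene_a})[other] = p.gene_b
    return groups, n_pairs


def _project_group(cfg, agene, members, models, introns, junctions):
    """Project all species' introns of one ortholog group onto anchor keys."""
    anchor = cfg.anchor
    ga = models[anchor].get(agene)
    if ga is None:
        return None, {}
    alns: dict[str, orthology.CodingAlignment] = {}
    sites: dict[tuple[int, int], _Site] = {}

    def site(off: int, phase: int) -> _Site:
        return sites.setdefault((off, phase), _Site(gene=agene, offset=off, phase=phase))

    for sp, gid in members.items():
        if sp == anchor:
            continue
        gb = models[sp].get(gid)
        if gb is None:
            continue
        aa, ab, _ = orthology.align_proteins(ga.protein, gb.protein)
        aln = orthology.codon_expand(
            OrthologPair(agene, gid), aa, ab, ga.spliced_cds, gb.spliced_cds
        )
        alns[sp] = aln
        calls = orthology.project_intron_sites(aln, introns[anchor][agene], introns[sp][gid])
        for c in calls:
            off = column_to_offset(aln.aligned_cds_a, c.aln_column)
            s = site(off, c.phase)
            if c.intron_a is not None:
                s.states[anchor] = PRESENT
                s.introns[anchor] = c.intron_a
                s.offsets[anchor] = c.intron_a.cds_offset
            if c.intron_b is not None:
                s.states[sp] = PRESENT
                s.introns[sp] = c.intron_b
                s.offsets[sp] = c.intron_b.cds_offset

    # absent vs unknown for species without an intron at each key
    for (off, phase), s in sites.items():
        for sp in cfg.fasta:
            if sp in s.states:
                continue
            if sp == anchor:
                s.states[sp] = ABSENT  # anchor annotation is direct
                s.offsets[sp] = off
                continue
            aln = alns.get(sp)
            if aln is None:
                s.states[sp] = UNKNOWN
                continue
            col = offset_to_column(aln.aligned_cds_a, off)
            left, right = orthology.flank_similarity(aln, col, cfg.flank_window)
            if min(left, right) >= cfg.min_similarity:
                s.states[sp] = ABSENT
                s.offsets[sp] = column_to_offset(aln.aligned_cds_b, col)
            else:
                s.states[sp] = UNKNOWN

    # quality filter: a low-quality neighbourhood in the focal-pair alignment
    # discards the site; in an outgroup pair it only makes that outgroup unknown
    focal_others = [f for f in cfg.focal if f != anchor]
    for (off, phase), s in sites.items():
        for sp, aln in alns.items():
            if s.states.get(sp) != PRESENT:
                continue
            col = offset_to_column(aln.aligned_cds_a, off)
            left, right = orthology.flank_similarity(aln, col, cfg.flank_window)
            if min(left, right) < cfg.min_similarity:
                if sp in focal_others:
                    s.discarded = "low_quality"
                else:
                    s.states[sp] = UNKNOWN

    # splice-junction confirmation of extant introns at discordant positions
    for s in sites.values():
        if all(v == PRESENT for v in s.states.values()):
            continue
        for sp, intr in s.introns.items():
            jx = junctions.get(sp)
            if jx is None:
                continue
            key = (intr.chrom_id, intr.genomic_start, intr.genomic_end)
            if jx.get(key, 0) < cfg.junction_min_reads:
                s.discarded = "junction"
    return alns, sites


def _assign_ordinals(site_list: list[_Site]) -> None:
    """Ancestral ordinals: rank by anchor offset among non-gain-like sites.

    Sites present in exactly one species are gain candidates and do not take
    part in the ancestral numbering.
    """
    ranked = [
        s for s in site_list
        if sum(1 for v in s.states.values() if v == PRESENT) > 1
    ]
    for rank, s in enumerate(sorted(ranked, key=lambda s: s.offset), start=1):
        s.ordinal = rank


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and return the summary dictionary.

    When ``cfg.outdir`` is set, the site, event and feature tables plus the
    stats JSON are written there.
    """
    cfg.validate()
    tree = SpeciesTree.from_newick(cfg.tree_newick)
    models, introns, rejects = _load_genomes(cfg)
    junctions = {
        sp: orthology.read_junction_bed(path) for sp, path in cfg.junctions.items() if path
    }
    groups, n_pairs = _ortholog_groups(cfg)

    all_sites: list[_Site] = []
    group_alns: dict[str, dict] = {}
    for agene in sorted(groups):
        alns, sites = _project_group(cfg, agene, groups[agene], models, introns, junctions)
        if alns is None:
            continue
        group_alns[agene] = alns
        site_list = [s for s in sites.values() if not s.discarded]
        n_discarded = len(sites) - len(site_list)
        if n_discarded:
            logger.info("%s: %d sites discarded by quality/junction filters", agene, n_discarded)
        _assign_ordinals(site_list)
        all_sites.extend(sorted(sites.values(), key=lambda s: s.offset))

    # a site can lose its last confirmed intron to the quality demotion above;
    # with no present tip it carries no information and is dropped
    kept = [
        s
        for s in all_sites
        if not s.discarded and any(v == PRESENT for v in s.states.values())
    ]
    profiles = [
        parsimony.PresenceProfile(
            site_id=s.site_id,
            states=dict(s.states),
            meta={"gene": s.gene, "offset": s.offset, "phase": s.phase,
                  "ordinal": s.ordinal, "site": s},
        )
        for s in kept
    ]
    losses = parsimony.loss_calls(profiles, tree, focal_species=tuple(cfg.focal))
    gains = parsimony.putative_gain_calls(profiles, tree)
    gains = [g for g in gains if g.branch in cfg.focal]

    features = _loss_feature_table(cfg, losses, models, groups, group_alns, kept)
    summary = _summarize(cfg, tree, models, introns, rejects, n_pairs, kept,
                         losses, gains, features, groups, group_alns)
    if cfg.outdir:
        _write_outputs(cfg, kept, losses, gains, features, summary)
    return summary


def _bearer_of(site: _Site, focal: str, other_focal: str, tree_tips) -> str | None:
    if site.states.get(other_focal) == PRESENT:
        return other_focal
    for sp in tree_tips:
        if sp != focal and site.states.get(sp) == PRESENT:
            return sp
    return None


def _loss_feature_table(cfg, losses, models, groups, group_alns, kept_sites):
    anchor = cfg.anchor
    tips = tuple(cfg.fasta)
    # conserved flank GC per (gene, species) for relative GC
    conserved_gc: dict[tuple[str, str], list[float]] = {}
    for s in kept_sites:
        if not all(s.states.get(f) == PRESENT for f in cfg.focal):
            continue
        for sp in cfg.focal:
            gid = groups.get(s.gene, {}).get(sp)
            if gid is None or sp not in s.offsets:
                continue
            g = models[sp].get(gid)
            if g is None:
                continue
            ctx = loss_features.flank_gc(g, _pseudo_intron(s.offsets[sp]), cfg.gc_window)
            if ctx.pooled_gc is not None:
                conserved_gc.setdefault((s.gene, sp), []).append(ctx.pooled_gc)

    rows = []
    for ev in losses:
        s: _Site = ev.meta["site"]
        focal = ev.branch
        other = [f for f in cfg.focal if f != focal]
        other_focal = other[0] if other else anchor
        bearer = _bearer_of(s, focal, other_focal, tips)
        if bearer is None:
            continue
        gid_f = groups[s.gene].get(focal)
        gene_f = models[focal].get(gid_f) if gid_f else None
        if gene_f is None or focal not in s.offsets:
            continue
        off_f = s.offsets[focal]
        intr_b = s.introns[bearer]
        gid_b = groups[s.gene][bearer]
        gene_b = models[bearer][gid_b]
        # precision on the alignment between the anchor and the non-anchor party
        aln_sp = focal if focal != anchor else bearer
        aln = group_alns[s.gene].get(aln_sp)
        if aln is None:
            continue
        col = offset_to_column(aln.aligned_cds_a, s.offset)
        precise, indel_bp = loss_features.classify_precision(col, aln, cfg.precision_window)
        up = gene_b.spliced_cds[: intr_b.cds_offset]
        down = gene_b.spliced_cds[intr_b.cds_offset :]
        rep5, rep3 = loss_features.direct_repeat_length(
            up, intr_b.sequence, down, cfg.repeat_k_max
        )
        ctx = loss_features.flank_gc(gene_f, _pseudo_intron(off_f), cfg.gc_window)
        rel_gc = (
            loss_features.relative_flank_gc(ctx.pooled_gc, conserved_gc.get((s.gene, focal), []))
            if ctx.pooled_gc is not None
            else None
        )
        # counterpart: the extant intron's flanks in the retaining focal species
        rel_gc_counterpart = None
        if bearer == other_focal and bearer in s.offsets:
            ctx_b = loss_features.flank_gc(gene_b, _pseudo_intron(s.offsets[bearer]), cfg.gc_window)
            if ctx_b.pooled_gc is not None:
                rel_gc_counterpart = loss_features.relative_flank_gc(
                    ctx_b.pooled_gc, conserved_gc.get((s.gene, bearer), [])
                )
        rows.append(
            {
                "loss_id": f"{focal}:{s.site_id}",
                "species": focal,
                "gene": s.gene,
                "ordinal": s.ordinal,
                "precise": precise,
                "flank_indel_bp": indel_bp,
                "relative_position": intr_b.cds_offset / len(gene_b.spliced_cds),
                "intron_length": intr_b.length,
                "repeat_len_5p": rep5,
                "repeat_len_3p": rep3,
                "flank_gc": ctx.pooled_gc,
                "relative_gc": rel_gc,
                "relative_gc_counterpart": rel_gc_counterpart,
                "fourfold_gc": loss_features.fourfold_gc(
                    gene_f, _pseudo_intron(off_f), cfg.gc_window
                ),
            }
        )
    return rows


def _pseudo_intron(offset: int) -> Intron:
    return Intron(gene_id="", ordinal=0, cds_offset=offset, phase=offset % 3, length=0, sequence="")


def _summarize(cfg, tree, models, introns, rejects, n_pairs, kept_sites,
               losses, gains, features, groups, group_alns) -> dict:
    rng_seed = cfg.seed
    summary: dict = {
        "run_id": cfg.run_id,
        "seed": cfg.seed,
        "version": __version__,
        "ortholog_pairs": n_pairs,
        "n_rejected_genes": {sp: len(r) for sp, r in rejects.items()},
        "n_sites": len(kept_sites),
        "n_conserved_sites": sum(
            1 for s in kept_sites if all(s.states.get(f) == PRESENT for f in cfg.focal)
        ),
        "n_discordant_sites": sum(
            1
            for s in kept_sites
            if sum(1 for f in cfg.focal if s.states.get(f) == PRESENT) == 1
        ),
        "species": {},
        "loss_records": [],
        "gain_records": [],
    }

    feat_by_sp = {}
    for row in features:
        feat_by_sp.setdefault(row["species"], []).append(row)
        summary["loss_records"].append(
            {
                "species": row["species"],
                "gene": row["gene"],
                "ordinal": row["ordinal"],
                "precise": row["precise"],
            }
        )
    for g in gains:
        summary["gain_records"].append(
            {"species": g.branch, "gene": g.meta["gene"], "offset": g.meta["offset"]}
        )

    # per-species statistics
    conserved_sites = [
        s for s in kept_sites if all(s.states.get(f) == PRESENT for f in cfg.focal)
    ]
    for focal in cfg.focal:
        rows = feat_by_sp.get(focal, [])
        lost_by_gene: dict[str, list[int]] = {}
        for r in rows:
            lost_by_gene.setdefault(r["gene"], []).append(r["ordinal"])
        observed_pairs = loss_features.adjacent_loss_pairs(lost_by_gene)

        # pool: every ranked site where the species is present, plus its losses
        pool_entries = [
            (s.gene, s.ordinal)
            for s in kept_sites
            if s.ordinal and s.states.get(focal) == PRESENT
        ]
        pool_entries += [(r["gene"], r["ordinal"]) for r in rows]
        pool_entries = sorted(set(pool_entries))
        n_lost = len(rows)
        resamp = None
        if n_lost and len(pool_entries) > n_lost:
            pool = stats.IntronPool(pool_entries, n_lost)
            resamp = stats.resample_adjacent_pairs(
                pool, observed_pairs, R=cfg.resample_R, seed=rng_seed
            )
        # exact independence null conditioned on per-gene loss counts
        site_count_by_gene: dict[str, int] = {}
        for s in kept_sites:
            if s.ordinal:
                site_count_by_gene[s.gene] = max(site_count_by_gene.get(s.gene, 0), s.ordinal)
        null_genes = [
            (site_count_by_gene.get(g, max(o)), len(o)) for g, o in lost_by_gene.items()
        ]
        exact = (
            stats.adjacency_null_distribution(null_genes, observed=observed_pairs)
            if null_genes
            else None
        )

        lost_pos = [r["relative_position"] for r in rows]
        lost_len = [r["intron_length"] for r in rows]
        lost_gc = [r["flank_gc"] for r in rows if r["flank_gc"] is not None]
        cons_pos, cons_len, cons_gc = [], [], []
        extant_pos = []
        for s in kept_sites:
            if s.states.get(focal) == PRESENT and focal in s.introns:
                gid = groups[s.gene].get(focal)
                g = models[focal].get(gid) if gid else None
                if g is not None:
                    extant_pos.append(s.introns[focal].cds_offset / len(g.spliced_cds))
        for s in conserved_sites:
            gid = groups[s.gene].get(focal)
            g = models[focal].get(gid) if gid else None
            if g is None or focal not in s.introns:
                continue
            intr = s.introns[focal]
            cons_pos.append(intr.cds_offset / len(g.spliced_cds))
            cons_len.append(intr.length)
            ctx = loss_features.flank_gc(g, _pseudo_intron(intr.cds_offset), cfg.gc_window)
            if ctx.pooled_gc is not None:
                cons_gc.append(ctx.pooled_gc)

        sp_stats: dict = {
            "n_losses": n_lost,
            "n_precise": sum(1 for r in rows if r["precise"]),
            "n_imprecise": sum(1 for r in rows if not r["precise"]),
            "n_extant": len(pool_entries) - n_lost,
            "n_gains": sum(1 for g in gains if g.branch == focal),
            "adjacent_pairs_observed": observed_pairs,
        }
        if resamp is not None:
            sp_stats["resampling"] = {
                "p": resamp.p_value,
                "p_shrunk": resamp.p_value_shrunk,
                "R": resamp.replicates,
                "tail": resamp.tail_count,
                "seed": resamp.seed,
            }
        if exact is not None:
            sp_stats["independence_null_p"] = exact.tail_p
        if len(extant_pos) >= 3:
            sp_stats["extant_position_wilcoxon_p_less"] = stats.wilcoxon_signed_rank(
                extant_pos, alternative="less"
            )
        if lost_pos and cons_pos:
            _, p2 = stats.mann_whitney_u(lost_pos, cons_pos)
            _, pg = stats.mann_whitney_u(lost_pos, cons_pos, alternative="greater")
            sp_stats["position_lost_vs_conserved"] = {"p": p2, "p_greater": pg}
        if lost_len and cons_len:
            _, p2 = stats.mann_whitney_u(lost_len, cons_len)
            _, pl = stats.mann_whitney_u(lost_len, cons_len, alternative="less")
            sp_stats["length_lost_vs_conserved"] = {"p": p2, "p_less": pl}
        if lost_gc and cons_gc:
            _, p2 = stats.mann_whitney_u(lost_gc, cons_gc)
            _, pg = stats.mann_whitney_u(lost_gc, cons_gc, alternative="greater")
            sp_stats["flank_gc_lost_vs_conserved"] = {
                "p": p2,
                "p_greater": pg,
                "median_lost": float(np.median(lost_gc)),
                "median_conserved": float(np.median(cons_gc)),
            }
        rel_lost = [r["relative_gc"] for r in rows if r["relative_gc"] is not None]
        rel_cp = [
            r["relative_gc_counterpart"] for r in rows if r["relative_gc_counterpart"] is not None
        ]
        if rel_lost and rel_cp:
            _, pg = stats.mann_whitney_u(rel_lost, rel_cp, alternative="greater")
            sp_stats["relative_gc_lost_vs_counterpart_p_greater"] = pg
        summary["species"][focal] = sp_stats

    # loss-rate contrast between the two focal species
    if len(cfg.focal) == 2:
        a, b = cfg.focal
        n_annot = {sp: sum(len(v) for v in introns[sp].values()) for sp in cfg.focal}
        la = summary["species"][a]["n_losses"]
        lb = summary["species"][b]["n_losses"]
        chi2, p = stats.chi_square_2x2(la, n_annot[a], lb, n_annot[b])
        summary["loss_rate_chi2"] = {
            "table": [la, n_annot[a], lb, n_annot[b]],
            "chi2": chi2,
            "p": p,
        }

    # gain-source evidence
    gain_meta = {}
    for g in gains:
        focal = g.branch
        gid = groups[g.meta["gene"]].get(focal)
        site = g.meta["site"]
        if gid is None or focal not in site.introns:
            continue
        intr = site.introns[focal]
        qid = f"{gid}:{intr.cds_offset}"
        gain_meta[qid] = {
            "length": intr.length,
            "locus": (intr.chrom_id, intr.genomic_start, intr.genomic_end),
            "canonical_boundaries": splice_boundary_check(intr.sequence),
            "species": focal,
        }
    n_with_source = 0
    source_verdicts: dict[str, int] = {}
    for sp, path in cfg.gain_hits.items():
        if not path or not os.path.exists(path):
            continue
        hits = orthology.read_blast_tab(path)
        hits = [h for h in hits if h.query_id in gain_meta]
        if not hits:
            continue
        cands = filter_source_hits(
            hits,
            {q: m["length"] for q, m in gain_meta.items()},
            {q: m["locus"] for q, m in gain_meta.items()},
        )
        retained_q = set()
        for c in cands:
            source_verdicts[c.verdict] = source_verdicts.get(c.verdict, 0) + 1
            if c.verdict == "retained":
                retained_q.add(c.intron_id)
        n_with_source += len(retained_q)
    summary["gains_with_source"] = n_with_source
    summary["gain_source_verdicts"] = source_verdicts
    summary["n_gains_total"] = len(gains)
    return summary


def _write_outputs(cfg, kept_sites, losses, gains, features, summary) -> None:
    os.makedirs(cfg.outdir, exist_ok=True)

    def tsv(path, header, rows):
        with open(os.path.join(cfg.outdir, path), "w") as fh:
            fh.write("\t".join(header) + "\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")

    tsv(
        "sites.tsv",
        ["site_id", "gene", "offset", "phase", "ordinal"] + list(cfg.fasta),
        [
            [s.site_id, s.gene, s.offset, s.phase, s.ordinal]
            + [s.states.get(sp, UNKNOWN) for sp in cfg.fasta]
            for s in kept_sites
        ],
    )
    tsv(
        "events.tsv",
        ["site_id", "event", "branch", "species"],
        [[e.site_id, e.event, e.branch, "+".join(e.species)] for e in losses + gains],
    )
    if features:
        cols = list(features[0])
        tsv("features.tsv", cols, [[r[c] for c in cols] for r in features])
    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def report(summary: dict) -> str:
    """Deterministic human-readable rendering of a run summary."""
    lines = [
        f"intronevo {summary.get('version', __version__)}  run={summary.get('run_id', '')}"
        f"  seed={summary.get('seed')}",
        f"sites: {summary.get('n_sites', 0)} total, "
        f"{summary.get('n_conserved_sites', 0)} conserved, "
        f"{summary.get('n_discordant_sites', 0)} discordant",
    ]
    for sp in sorted(summary.get("species", {})):
        st = summary["species"][sp]
        lines.append(
            f"[{sp}] losses: {st['n_losses']} ({st['n_precise']} precise, "
            f"{st['n_imprecise']} imprecise); extant: {st['n_extant']}; "
            f"putative gains: {st['n_gains']}"
        )
        lines.append(f"[{sp}] adjacent loss pairs observed: {st['adjacent_pairs_observed']}")
        if "resampling" in st:
            r = st["resampling"]
            lines.append(
                f"[{sp}] resampling p = {r['p']:.4g} (tail {r['tail']}/{r['R']}, "
                f"shrunk {r['p_shrunk']:.4g}, seed {r['seed']})"
            )
        if "independence_null_p" in st:
            lines.append(f"[{sp}] exact independence-null p = {st['independence_null_p']:.4g}")
    if "loss_rate_chi2" in summary:
        c = summary["loss_rate_chi2"]
        lines.append(
            f"loss-rate 2x2 {c['table']}: chi2 = {c['chi2']:.2f}, p = {c['p']:.3g}"
        )
    lines.append(
        f"putative gains total: {summary.get('n_gains_total', 0)}; "
        f"with identified source: {summary.get('gains_with_source', 0)}"
    )
    return "\n".join(lines)
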