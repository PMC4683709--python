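"""Per-site features that discriminate the loss mechanisms.

Direct repeats at intron boundaries (NHEJ signature), exonic flank GC and
its gene-relative version (biased gene conversion signature), relative
position (3' bias under reverse transcription), and 4-fold-site GC.
"""

from intronevo import (
    GeneModel,
    Intron,
    direct_repeat_length,
    flank_gc,
    fourfold_gc,
    relative_flank_gc,
    relative_intron_position,
)

cds = ("ATGGCTGGTCCAACTGGTGCAGAT" * 20)[:480]
gene = GeneModel("toy", "SP", "c1", "+", [(0, 480)], cds, "", chrom_seq=cds)
intron = Intron("toy", 1, 120, 0, 80, "GT" + "A" * 76 + "AG")

print(f"relative position: {relative_intron_position(intron, gene):.2f} (0 = 5' end)")
ctx = flank_gc(gene, intron, window=100)
print(f"flank GC (100 bp each side): {ctx.pooled_gc:.3f}")
print(f"relative GC vs conserved medians [0.40, 0.50, 0.55]: "
      f"{relative_flank_gc(ctx.pooled_gc, [0.40, 0.50, 0.55]):.2f}")
print(f"4-fold degenerate site GC: {fourfold_gc(gene, intron, window=100):.2f}")

# boundary repeats: upstream exon and intron both end ...TCAG
rep5, rep3 = direct_repeat_length("AACTGGTCAG", "GTAAATTTCAG", "TTTGCA")
print(f"direct repeats: 5' = {rep5} bp, 3' = {rep3} bp")

# A repeat of r bp at either boundary permits a deletion that removes the
# intron precisely without leaving an exonic scar; elevated flank or
# relative GC points instead at gene conversion with a cDNA template.
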