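"""Dollo parsimony on intron presence/absence profiles.

Each intron position is a binary character gained at most once; the
reconstruction places the origin at the MRCA of the intron-bearing species
and explains confirmed absences with the fewest losses.
"""

from intronevo import PresenceProfile, SpeciesTree, dollo_reconstruct, putative_gain_calls

tree = SpeciesTree.from_newick()  # ((((DDB,DPU),PPA),DFA),EHI)

profiles = {
    "terminal loss in DPU": {"DDB": "present", "DPU": "absent", "PPA": "present",
                             "DFA": "present", "EHI": "present"},
    "origin above DDB+PPA": {"DDB": "present", "DPU": "absent", "PPA": "present",
                             "DFA": "absent", "EHI": "absent"},
    "gain in DDB": {"DDB": "present", "DPU": "absent", "PPA": "absent",
                    "DFA": "absent", "EHI": "absent"},
    "unknown blocks gain": {"DDB": "present", "DPU": "absent", "PPA": "unknown",
                            "DFA": "absent", "EHI": "absent"},
}

for label, states in profiles.items():
    p = PresenceProfile(site_id=label, states=states)
    events = dollo_reconstruct(p, tree)
    gains = putative_gain_calls([p], tree)
    ev = ", ".join(f"{e.event}@{e.branch}" for e in events)
    print(f"{label:24s} -> {ev}; strict gain call: {bool(gains)}")

# The first event is always the single origin (gain at the MRCA of present
# tips); losses follow. The strict gain criterion additionally demands
# confirmed absence in all four other species, so an 'unknown' blocks it.
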