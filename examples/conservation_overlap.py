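"""Human-mouse conservation by 7mer seed identity.

Builds small human and mouse mature-miRNA sets (miR-182-5p shared, plus
species-specific entries) and prints the seed-family overlap the way a
cross-species expression comparison would use it.
"""

from mirseed import MatureMiRNA, conserved_between, seed_families

human = [
    MatureMiRNA(id="hsa-miR-182-5p", sequence="UUUGGCAAUGGUAGAACUCACACU"),
    MatureMiRNA(id="hsa-miR-96-5p", sequence="UUUGGCACUAGCACAUUUUUGCU"),
    MatureMiRNA(id="hsa-miR-33b-5p", sequence="GUGCAUUGCUGUUGCAUUGC"),
]
mouse = [
    MatureMiRNA(id="mmu-miR-182-5p", sequence="UUUGGCAAUGGUAGAACUCACACU"),
    MatureMiRNA(id="mmu-miR-201-5p", sequence="UACUCAGUAAGGCAUUGUUCUU"),
]

res = conserved_between(human, mouse)
print(f"shared seed families: {res.n_shared_families}")
print(f"human miRNAs with a murine seed match: {res.n_a_mirnas_shared}")
print(f"human-only miRNAs: {res.n_a_mirnas_only}")
print(f"mouse-only miRNAs: {res.n_b_mirnas_only}")

for fam in seed_families(human + mouse):
    print(f"  seed {fam.seed}: {', '.join(i for _, i in fam.members)}")

print(
    "\nA miRNA counts as conserved when nucleotides 2-8 are identical across"
    " species; miR-182-5p shares its seed between human and mouse, which is"
    " what qualifies it for cross-species validation."
)
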