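"""Annotate planted seed sites with their binding-context features.

Generates one synthetic 3'-UTR with two planted miR-182-5p sites, scans it,
and prints local AU content, 3'-supplementary pairing, positional features
and cooperative partners for each site.
"""

from mirseed import MatureMiRNA, annotate, scan_utr
from mirseed.seedsites import SiteType
from mirseed.synthetic import gen_utrs

mir182 = MatureMiRNA(id="hsa-miR-182-5p", sequence="UUUGGCAAUGGUAGAACUCACACU")
utrs, truth = gen_utrs(
    n=1, length=400, gc=0.55, seed=4,
    plants=[(0, mir182, SiteType.MER7_M8, 60), (0, mir182, SiteType.MER8, 90)],
)
utr = utrs[0]
sites = scan_utr(mir182, utr)

for site in sites:
    ctx = annotate(mir182, utr, site, all_sites=sites)
    print(f"{site.site_type.label:<12} at [{site.start},{site.end})  motif {site.motif}")
    print(f"  local AU content (60 nt window): {ctx.local_au:.3f}")
    print(f"  3'-supplementary contiguous pairs (nt 12-17): {ctx.tp_pairing}")
    print(f"  dist to stop codon: {ctx.dist_stop} nt, dist to 3' end: {ctx.dist_end} nt,"
          f" rel. position {ctx.rel_pos:.3f}, near stop: {ctx.near_stop}")
    print(f"  cooperative partners (gap 8-40 nt): {list(ctx.coop_partners)}")

print(
    "\nHigh AU flanks, extra 3' pairing, a non-central position and a nearby"
    " partner site are the classical conditions favouring effective repression;"
    " the tool reports them as independent features without a combined score."
)
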