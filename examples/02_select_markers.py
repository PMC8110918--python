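"""Marker selection on simulated data with a planted co-expression block.

Simulates 5 true markers of one cell type plus 6 decoy genes, lists all 11
as candidates, and shows the similarity filter recovering exactly the
planted block at the 0.6 threshold.
"""
from pdacmarkers import select_markers, selection_report, fixture_suite

ds = fixture_suite()["clean_block"]
catalog = ds.candidate_catalog(decoys_per_type=6)

results, derived = select_markers(ds.matrix, catalog, threshold=0.6)

print(selection_report(results).to_string(index=False))
print("\nplanted markers :", sorted(ds.truth["B cells"]))
print("selected markers:", sorted(results[0].selected))

# The report shows 11 candidates reduced to 5 selected genes with a set
# mean similarity near 1; the selected set equals the planted truth, and
# the derived catalog is ready for cell scoring.
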