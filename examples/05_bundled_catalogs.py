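"""The bundled PDAC marker-gene catalogs.

Prints the headline counts of the candidate (PDAC-cMG) and selected
(PDAC-MGIC) catalogs and compares the selected catalog to the default
nSolver cell-type definitions.
"""
from pdacmarkers import load_catalog

cmg = load_catalog("pdac_cmg")
mgic = load_catalog("pdac_mgic")
default = load_catalog("nsolver_default")

print(f"PDAC-cMG   : {len(cmg.unique_genes())} unique genes, {len(cmg)} cell types")
print(f"PDAC-MGIC  : {len(mgic.unique_genes())} unique genes, {len(mgic)} cell types")
print(f"nSolver    : {len(default.unique_genes())} genes, {len(default)} cell types")

new = sorted(set(mgic.cell_types) - set(default.cell_types))
print(f"\ncell types newly defined vs the nSolver default ({len(new)}):")
for ct in new:
    print(f"  {ct}: {', '.join(mgic[ct].genes)}")

print("\nB-cell definition, candidates -> selected:")
print("  candidates:", ", ".join(cmg["B cells"].genes))
print("  selected  :", ", ".join(mgic["B cells"].genes))

# 90 candidates over 23 cell types are narrowed to 55 markers over 22 cell
# types; 8 cell types (plasma B, regulatory B, two conventional DC subsets,
# APCs, M2 macrophages, monocytes, CD4+ T) have no counterpart in the
# default definitions.
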