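"""I/O, transforms, detection filtering and the bundled catalogs."""
import numpy as np
import pytest

import pdacmarkers as pm

# -- plain matrix round trip ---------------------------------------------------


def make_tsv(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_expression_dimensions_and_symbols(tmp_path):
    p = make_tsv(tmp_path, "gene\tS1\tS2\n cd19 \t1\t2\nMS4A1\t3\t4\nBLK\t5\t6\n")
    m = pm.read_expression(p)
    assert m.gene_ids == ["CD19", "MS4A1", "BLK"]
    assert m.sample_ids == ["S1", "S2"]
    assert m.values.shape == (3, 2)
    assert m.scale is pm.Scale.LINEAR


def test_round_trip_identity(tmp_path, small_log2_matrix):
    out = tmp_path / "rt.tsv"
    pm.write_expression(small_log2_matrix, out)
    back = pm.read_expression(out, scale=pm.Scale.LOG2)
    assert back.gene_ids == small_log2_matrix.gene_ids
    assert back.sample_ids == small_log2_matrix.sample_ids
    np.testing.assert_allclose(back.values, small_log2_matrix.values, rtol=1e-12)


def test_duplicate_symbols_rejected(tmp_path):
    p = make_tsv(tmp_path, "gene\tS1\nCD19\t1\ncd19\t2\n")
    with pytest.raises(pm.DuplicateGeneError, match="CD19"):
        pm.read_expression(p)


def test_non_numeric_cell_named(tmp_path):
    p = make_tsv(tmp_path, "gene\tS1\tS2\nCD19\t1\tNA\nBLK\t2\t3\n")
    with pytest.raises(pm.ParseError, match="NA.*CD19.*S2"):
        pm.read_expression(p)


# -- RCC -----------------------------------------------------------------------

RCC_TEMPLATE = """<Header>
FileVersion,1.7
</Header>
<Sample_Attributes>
ID,{sample}
Date,20190101
</Sample_Attributes>
<Lane_Attributes>
ID,1
</Lane_Attributes>
<Code_Summary>
CodeClass,Name,Accession,Count
{rows}
</Code_Summary>
"""


def write_rcc(tmp_path, sample, rows):
    body = "\n".join(",".join(r) for r in rows)
    p = tmp_path / f"{sample}.RCC"
    p.write_text(RCC_TEMPLATE.format(sample=sample, rows=body))
    return p


PANEL = [
    ("Endogenous", "CD19", "NM_1", "120"),
    ("Endogenous", "MS4A1", "NM_2", "80"),
    ("Endogenous", "CD3D", "NM_3", "200"),
    ("Endogenous", "CD3E", "NM_4", "150"),
    ("Endogenous", "PTPRC", "NM_5", "900"),
    ("Endogenous", "CD8A", "NM_6", "60"),
    ("Housekeeping", "GAPDH", "NM_7", "5000"),
    ("Housekeeping", "ACTB", "NM_8", "8000"),
    ("Positive", "POS_A", "ERCC_1", "1000"),
    ("Negative", "NEG_A", "ERCC_2", "5"),
]


def test_read_rcc_merges_and_classifies(tmp_path):
    p1 = write_rcc(tmp_path, "PDAC01", PANEL)
    p2 = write_rcc(tmp_path, "PDAC02", [(c, n, a, str(float(v) * 2)) for c, n, a, v in PANEL])
    m = pm.read_rcc([p1, p2])
    assert m.n_genes == 10 and m.sample_ids == ["PDAC01", "PDAC02"]
    assert m.class_of("GAPDH") is pm.GeneClass.HOUSEKEEPING
    assert m.class_of("NEG_A") is pm.GeneClass.NEGATIVE_CONTROL
    assert m.class_of("CD19") is pm.GeneClass.ENDOGENOUS
    assert m.gene_values("CD19").tolist() == [120.0, 240.0]


def test_read_rcc_panel_mismatch(tmp_path):
    p1 = write_rcc(tmp_path, "A", PANEL)
    p2 = write_rcc(tmp_path, "B", PANEL[:-1])
    with pytest.raises(pm.ParseError, match="panel"):
        pm.read_rcc([p1, p2])


def test_read_rcc_malformed_section(tmp_path):
    p = tmp_path / "bad.RCC"
    p.write_text("<Sample_Attributes>\nID,X\n</Sample_Attributes>\n")
    with pytest.raises(pm.ParseError, match="Code_Summary"):
        pm.read_rcc([p])


# -- transforms ----------------------------------------------------------------


def test_log2_transform_values_and_flag():
    m = pm.ExpressionMatrix(["G1"], ["S1", "S2", "S3"], np.array([[0.0, 3.0, 7.0]]))
    t = pm.log2_transform(m, offset=1.0)
    np.testing.assert_allclose(t.values, [[0.0, 2.0, 3.0]])
    assert t.scale is pm.Scale.LOG2
    with pytest.raises(pm.ScaleError):
        pm.log2_transform(t)


def test_log2_transform_monotone(rng):
    vals = rng.uniform(0, 100, size=(5, 8))
    m = pm.ExpressionMatrix([f"G{i}" for i in range(5)], [f"S{j}" for j in range(8)], vals)
    t = pm.log2_transform(m)
    for i in range(5):
        assert (np.argsort(t.values[i]) == np.argsort(vals[i])).all()


def test_normalize_housekeeping_identity_and_scaling():
    vals = np.array([[10.0, 10.0], [4.0, 4.0], [7.0, 13.0]])
    m = pm.ExpressionMatrix(["HK1", "HK2", "G1"], ["S1", "S2"], vals)
    out = pm.normalize_housekeeping(m, ["HK1", "HK2"])
    np.testing.assert_allclose(out.values, vals)  # constant HK -> unchanged

    # sample 2's HK geometric mean is twice sample 1's -> halved relative to it
    vals2 = np.array([[4.0, 8.0], [9.0, 18.0], [10.0, 10.0]])
    m2 = pm.ExpressionMatrix(["HK1", "HK2", "G1"], ["S1", "S2"], vals2)
    out2 = pm.normalize_housekeeping(m2, ["HK1", "HK2"])
    geo = np.array([6.0, 12.0])
    factors = geo.mean() / geo
    np.testing.assert_allclose(out2.values, vals2 * factors[None, :])


def test_normalize_housekeeping_errors():
    m = pm.ExpressionMatrix(["HK1", "G1"], ["S1", "S2"], np.array([[1.0, 0.0], [2.0, 3.0]]))
    with pytest.raises(pm.MissingGeneError, match="HKX"):
        pm.normalize_housekeeping(m, ["HKX"])
    with pytest.raises(pm.PdacMarkersError, match="positive"):
        pm.normalize_housekeeping(m, ["HK1"])


# -- detection filter ----------------------------------------------------------


def test_detection_filter_boundary_inclusive():
    # detected in exactly 3 of 6 samples passes min_fraction=0.5
    vals = np.array(
        [
            [9.0, 9.0, 9.0, 1.0, 1.0, 1.0],
            [9.0, 9.0, 1.0, 1.0, 1.0, 1.0],
            [9.0, 9.0, 9.0, 9.0, 9.0, 9.0],
        ]
    )
    m = pm.ExpressionMatrix(["HALF", "THIRD", "ALWAYS"], [f"S{i}" for i in range(6)], vals)
    kept, dropped = pm.detection_filter(m, threshold=5.0, min_fraction=0.5)
    assert kept.gene_ids == ["HALF", "ALWAYS"]
    assert dropped == ["THIRD"]


def test_detection_filter_identity_and_idempotence(rng):
    vals = rng.uniform(1, 100, size=(10, 6))
    m = pm.ExpressionMatrix([f"G{i}" for i in range(10)], [f"S{j}" for j in range(6)], vals)
    kept, dropped = pm.detection_filter(m, threshold=0.5)
    assert dropped == [] and kept.gene_ids == m.gene_ids
    again, dropped2 = pm.detection_filter(kept, threshold=0.5)
    assert dropped2 == []


def test_negative_control_threshold():
    vals = np.array([[100.0, 200.0], [4.0, 6.0], [5.0, 5.0]])
    m = pm.ExpressionMatrix(
        ["G1", "NEG1", "NEG2"],
        ["S1", "S2"],
        vals,
        gene_class={"NEG1": pm.GeneClass.NEGATIVE_CONTROL, "NEG2": pm.GeneClass.NEGATIVE_CONTROL},
    )
    neg = np.array([4.0, 6.0, 5.0, 5.0])
    assert pm.negative_control_threshold(m) == pytest.approx(neg.mean() + 2 * neg.std(ddof=1))


# -- catalogs ------------------------------------------------------------------


def test_bundled_catalog_counts():
    cmg = pm.load_catalog("pdac_cmg")
    mgic = pm.load_catalog("pdac_mgic")
    assert (len(cmg.unique_genes()), len(cmg)) == (90, 23)
    assert (len(mgic.unique_genes()), len(mgic)) == (55, 22)
    assert mgic["B cells"].genes == ["BLK", "CD19", "CD22", "CR2", "MS4A1"]
    assert "Plasmacytoid Dendritic cells" in cmg.cell_types
    assert "Plasmacytoid Dendritic cells" not in mgic.cell_types


def test_selected_catalog_nested_in_candidates():
    cmg = pm.load_catalog("pdac_cmg")
    mgic = pm.load_catalog("pdac_mgic")
    for entry in mgic:
        assert set(entry.genes) <= set(cmg[entry.name].genes)


def test_unknown_catalog_name():
    with pytest.raises(pm.CatalogError, match="unknown catalog"):
        pm.load_catalog("nope")


def test_catalog_yaml_round_trip(tmp_path):
    cat = pm.load_catalog("pdac_mgic")
    path = tmp_path / "cat.yaml"
    pm.write_catalog_yaml(cat, path)
    back = pm.read_catalog(path)
    assert back.cell_types == cat.cell_types
    assert all(back[ct].genes == cat[ct].genes for ct in cat.cell_types)
    assert back["Plasma B cells"].parent == "B cells"


def test_catalog_validation():
    with pytest.raises(pm.CatalogError, match="parent"):
        pm.GeneSetCatalog([pm.CellTypeDef("A", ["G1"], parent="MISSING")])
    with pytest.raises(pm.CatalogError, match="duplicate"):
        pm.CellTypeDef("A", ["G1", "g1"])


def test_intersect_catalog_warns_and_drops(small_log2_matrix):
    cat = pm.GeneSetCatalog(
        [
            pm.CellTypeDef("present", ["GENEA", "GENEB", "ABSENT1"]),
            pm.CellTypeDef("gone", ["ABSENT2"]),
        ]
    )
    with pytest.warns(pm.MarkerWarning, match="ABSENT"):
        restricted, missing = pm.intersect_catalog(small_log2_matrix, cat)
    assert restricted.cell_types == ["present"]
    assert restricted["present"].genes == ["GENEA", "GENEB"]
    assert missing == {"present": ["ABSENT1"], "gone": ["ABSENT2"]}
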