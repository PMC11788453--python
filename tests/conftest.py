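import pytest

from irae_som import load_catalog, load_category_matrix, load_unit_labels


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def published_matrix():
    """The packaged 8x21 drug-by-category reporting-ratio matrix."""
    return load_category_matrix()


@pytest.fixture(scope="session")
def published_units():
    """Published 6x1 unit assignment per drug (the tree's labels)."""
    return load_unit_labels()


@pytest.fixture(scope="session")
def published_partition(published_units):
    groups = {}
    for drug, unit in published_units.items():
        groups.setdefault(unit, set()).add(drug)
    return frozenset(frozenset(g) for g in groups.values())


def write_jader_csvs(tmp_path, demo_rows, drug_rows, reac_rows):
    """Write minimal canonical-format DEMO/DRUG/REAC files for parsing tests."""
    demo = tmp_path / "demo.csv"
    drug = tmp_path / "drug.csv"
    reac = tmp_path / "reac.csv"
    demo.write_text(
        "case_id,sex,age_band,weight_band\n"
        + "".join(f"{r[0]},{r[1] if len(r) > 1 else ''},,\n" for r in demo_rows)
    )
    drug.write_text(
        "case_id,drug_name,involvement\n"
        + "".join(f"{c},{d},{i}\n" for c, d, i in drug_rows)
    )
    reac.write_text(
        "case_id,pt_name,onset_date\n"
        + "".join(f"{c},{p},\n" for c, p in reac_rows)
    )
    return demo, drug, reac
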