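"""Twin-pair table I/O and sex residualization."""

import io

import numpy as np
import pandas as pd
import pytest

from twinace import TraitSpec, TwinDataError, TwinPairTable, read_twin_csv, residualize, simulate, write_twin_csv
from twinace.simulate import default_wellbeing_params

TRAITS2 = TraitSpec(["x", "y"])


def _write_read(table, tmp_path, traits):
    f = tmp_path / "t.csv"
    write_twin_csv(table, f)
    return read_twin_csv(f, traits), f


def test_traitspec_rejects_duplicates_and_empty():
    with pytest.raises(TwinDataError):
        TraitSpec(["a", "a"])
    with pytest.raises(TwinDataError):
        TraitSpec([])


def test_empty_file_gives_empty_table(tmp_path):
    f = tmp_path / "empty.csv"
    f.write_text("family_id,zygosity,sex1,sex2,x_1,x_2,y_1,y_2\n")
    t = read_twin_csv(f, TRAITS2)
    assert t.n_pairs == 0
    assert t.p == 2


def test_missing_column_is_named(tmp_path):
    f = tmp_path / "bad.csv"
    f.write_text("family_id,zygosity,sex1,sex2,x_1,x_2\n")
    with pytest.raises(TwinDataError, match="y_1"):
        read_twin_csv(f, TRAITS2)


def test_bad_zygosity_rows_rejected_and_logged(tmp_path):
    f = tmp_path / "z.csv"
    f.write_text(
        "family_id,zygosity,sex1,sex2,x_1,x_2\n"
        "f1,MZ,male,male,1.0,2.0\n"
        "f2,XX,male,male,1.0,2.0\n"
        "f3,dz,female,male,3.0,NA\n"
    )
    t = read_twin_csv(f, TraitSpec(["x"]))
    assert t.n_pairs == 2  # lowercase dz parses, XX does not
    assert any("zygosity" in msg for msg in t.log)
    assert set(t.data["zygosity"]) == {"MZ", "DZ"}


def test_all_missing_pairs_dropped(tmp_path):
    f = tmp_path / "m.csv"
    f.write_text(
        "family_id,zygosity,sex1,sex2,x_1,x_2\n"
        "f1,MZ,male,male,,\n"
        "f2,DZ,male,male,1.5,NA\n"
    )
    t = read_twin_csv(f, TraitSpec(["x"]))
    assert t.n_pairs == 1
    assert any("all trait values missing" in msg for msg in t.log)


def test_roundtrip_is_bitwise_lossless(tmp_path):
    params = default_wellbeing_params(nMZ=20, nDZ=30, missing_rate=0.15, seed=42)
    table = simulate(params)
    back, f = _write_read(table, tmp_path, params.traits)
    cols = params.traits.columns()
    orig, new = table.data[cols].to_numpy(), back.data[cols].to_numpy()
    assert np.array_equal(np.isnan(orig), np.isnan(new))
    m = ~np.isnan(orig)
    assert np.array_equal(orig[m], new[m])  # bit-for-bit via repr round-trip
    # second write reproduces the file bytes exactly
    f2 = tmp_path / "t2.csv"
    write_twin_csv(back, f2)
    assert f.read_text() == f2.read_text()


def test_study_scale_fixture_loads_1136_pairs(tmp_path):
    table = simulate(default_wellbeing_params(seed=5))
    back, f = _write_read(table, tmp_path, table.traits)
    assert back.n_pairs == 1136
    assert back.n_by_zygosity() == {"MZ": 429, "DZ": 707}
    assert len(f.read_text().splitlines()) == 1137  # header + one row per pair


def test_zero_pair_table_writes_header_only(tmp_path):
    t = TwinPairTable(
        pd.DataFrame(columns=["family_id", "zygosity", "sex1", "sex2", "x_1", "x_2"]),
        TraitSpec(["x"]),
    )
    f = tmp_path / "empty_out.csv"
    write_twin_csv(t, f)
    assert f.read_text().splitlines() == ["family_id,zygosity,sex1,sex2,x_1,x_2"]


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def _toy_table(values1, values2, sexes1, sexes2, zyg=None):
    n = len(values1)
    return TwinPairTable(
        pd.DataFrame({
            "family_id": [f"f{i}" for i in range(n)],
            "zygosity": zyg or ["MZ", "DZ"] * (n // 2),
            "sex1": sexes1,
            "sex2": sexes2,
            "x_1": values1,
            "x_2": values2,
        }),
        TraitSpec(["x"]),
    )


def test_residualize_balanced_null_effect_equals_centering():
    # male and female means are identical by construction (both 2.5), so the
    # fitted sex slope is exactly zero and residualizing reduces to centering
    v1, v2 = [1.0, 1.0, 4.0, 4.0], [2.0, 2.0, 3.0, 3.0]
    t = _toy_table(v1, v2, ["male", "female"] * 2, ["female", "male"] * 2)
    r = residualize(t)
    grand = 2.5
    np.testing.assert_allclose(r.data["x_1"], np.array(v1) - grand, atol=1e-10)
    np.testing.assert_allclose(r.data["x_2"], np.array(v2) - grand, atol=1e-10)


def test_residualize_removes_additive_sex_effect():
    params = default_wellbeing_params(nMZ=300, nDZ=400, seed=11, sex_effect=np.array([0.5, 0.0, 0.0]))
    table = simulate(params)
    r = residualize(table)
    sex = np.concatenate([
        (r.data["sex1"] == "female").to_numpy(float),
        (r.data["sex2"] == "female").to_numpy(float),
    ])
    for trait in params.traits.names:
        y = np.concatenate([r.data[f"{trait}_1"], r.data[f"{trait}_2"]])
        slope = np.polyfit(sex, y, 1)[0]
        assert abs(slope) < 1e-10
        # OLS residual variance never exceeds the original
        orig = np.concatenate([table.data[f"{trait}_1"], table.data[f"{trait}_2"]])
        assert np.var(y) <= np.var(orig) + 1e-12


def test_residualize_is_idempotent_and_commutes_with_row_order():
    params = default_wellbeing_params(nMZ=50, nDZ=80, seed=3, sex_effect=np.array([0.4, -0.2, 0.1]),
                                      missing_rate=0.1)
    table = simulate(params)
    once = residualize(table)
    twice = residualize(once)
    cols = params.traits.columns()
    np.testing.assert_allclose(once.data[cols], twice.data[cols], atol=1e-10)

    perm = np.random.default_rng(0).permutation(table.n_pairs)
    shuffled = TwinPairTable(table.data.iloc[perm].reset_index(drop=True), table.traits)
    r_shuffled = residualize(shuffled)
    np.testing.assert_allclose(
        r_shuffled.data[cols].to_numpy(),
        once.data[cols].to_numpy()[perm],
        atol=1e-10,
    )


def test_residualize_missing_sex_blanks_traits():
    t = _toy_table([1.0, 3.0, 2.0, 6.0], [3.0, 1.0, 6.0, 2.0],
                   [None, "female", "male", "female"], ["female", "male", "male", "female"])
    r = residualize(t)
    assert np.isnan(r.data.loc[0, "x_1"])
    assert not np.isnan(r.data.loc[0, "x_2"])
    assert any("sex1 missing" in msg for msg in r.log)


def test_residualize_constant_sex_is_degenerate():
    t = _toy_table([1.0, 2.0], [3.0, 4.0], ["male", "male"], ["male", "male"])
    with pytest.raises(TwinDataError, match="constant"):
        residualize(t)
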