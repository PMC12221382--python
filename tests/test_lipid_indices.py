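"""Mol%, lipid indices and their invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import adipomorph as am


def _table(quantities: dict[str, float], sample="s1", fraction="TG") -> pd.DataFrame:
    rows = [(sample, fraction, sp, q) for sp, q in quantities.items()]
    return pd.DataFrame(rows, columns=["sample", "fraction", "species", "quantity"])


class TestSpeciesNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("18:2 n-6", "C18:2n-6"),
            ("C16:1 n7", "C16:1n-7"),
            ("c16:0", "C16:0"),
            ("C20:4n-6", "C20:4n-6"),
            ("other", "other"),
        ],
    )
    def test_common_variants(self, raw, expected):
        assert am.normalize_species(raw) == expected

    def test_unknown_code_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="unrecognized"):
            assert am.normalize_species("cholesterol") == "cholesterol"


class TestMolPercent:
    def test_two_species_split(self):
        out = am.mol_percent(_table({"C16:0": 30.0, "C18:0": 70.0}))
        by_sp = out.set_index("species")["mol_percent"]
        assert by_sp["C16:0"] == pytest.approx(30.0)
        assert by_sp["C18:0"] == pytest.approx(70.0)

    def test_standard_excluded_and_rows_sum_to_100(self):
        out = am.mol_percent(_table({"C16:0": 10.0, "C18:0": 30.0, "C19:0": 99.0}))
        assert "C19:0" not in set(out["species"])
        assert out["mol_percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_naive_loop_on_random_table(self):
        rng = np.random.default_rng(0)
        species = ["C14:0", "C16:0", "C16:1n-7", "C18:0", "C18:1n-9", "C18:1n-7", "C18:2n-6", "C20:4n-6"]
        q = {sp: float(rng.uniform(0.1, 50)) for sp in species}
        out = am.mol_percent(_table(q)).set_index("species")["mol_percent"]
        total = sum(q.values())
        for sp in species:
            assert out[sp] == pytest.approx(100.0 * q[sp] / total, rel=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(am.ValidationError):
            am.mol_percent(_table({"C16:0": 0.0, "C18:0": 0.0}))


class TestComputeIndices:
    def test_worked_five_species_example(self, toy_fa_sample):
        idx = am.compute_indices(toy_fa_sample).iloc[0]
        assert idx["total_fa_vs_c19"] == pytest.approx(15.0, abs=1e-12)
        assert idx["elovl6_ratio"] == pytest.approx(0.5, abs=1e-12)
        assert idx["palmitoleate_linoleate"] == pytest.approx(0.2, abs=1e-12)
        assert idx["lipogenic_index"] == pytest.approx(0.8, abs=1e-12)

    def test_simple_ratios(self):
        idx = am.compute_indices(_table({"C16:0": 30.0, "C18:2n-6": 15.0, "C16:1n-7": 30.0})).iloc[0]
        assert idx["lipogenic_index"] == pytest.approx(2.0)
        assert idx["scd1_ratio"] == pytest.approx(1.0)

    def test_missing_species_yields_nan_not_fabrication(self):
        with pytest.warns(UserWarning, match="missing"):
            idx = am.compute_indices(_table({"C16:0": 30.0, "C18:0": 10.0})).iloc[0]
        assert np.isnan(idx["lipogenic_index"])
        assert idx["elovl6_ratio"] == pytest.approx(10.0 / 30.0)

    def test_alternative_elovl6_definition(self):
        t = _table({"C16:1n-7": 4.0, "C18:1n-7": 1.0, "C16:0": 10.0, "C18:0": 5.0})
        default = am.compute_indices(t).iloc[0]["elovl6_ratio"]
        alt = am.compute_indices(t, elovl6_definition="C18:1n-7/C16:1n-7").iloc[0]["elovl6_ratio"]
        assert default == pytest.approx(0.5)
        assert alt == pytest.approx(0.25)

    def test_indices_agree_between_quantity_and_mol_percent_scales(self):
        rng = np.random.default_rng(3)
        species = ["C16:0", "C16:1n-7", "C18:0", "C18:2n-6", "C20:4n-6"]
        q = {sp: float(rng.uniform(0.5, 40)) for sp in species}
        from_q = am.compute_indices(_table(q)).iloc[0]
        mol = am.mol_percent(_table(q))
        mol_q = dict(zip(mol["species"], mol["mol_percent"]))
        from_mol = am.compute_indices(_table(mol_q)).iloc[0]
        for col in ("lipogenic_index", "palmitoleate_linoleate", "scd1_ratio", "elovl6_ratio"):
            assert from_q[col] == pytest.approx(from_mol[col], rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        species = ["C16:0", "C16:1n-7", "C18:0", "C18:2n-6", "C19:0"]
        q = {sp: float(rng.uniform(0.5, 40)) for sp in species}
        base = am.compute_indices(_table(q)).iloc[0]
        scaled_all = am.compute_indices(_table({sp: v * c for sp, v in q.items()})).iloc[0]
        for col in ("lipogenic_index", "palmitoleate_linoleate", "scd1_ratio", "elovl6_ratio", "total_fa_vs_c19"):
            assert scaled_all[col] == pytest.approx(base[col], rel=1e-9)
        # scaling only the non-standard quantities scales total_fa_vs_c19 by c
        scaled_non_std = am.compute_indices(
            _table({sp: (v * c if sp != "C19:0" else v) for sp, v in q.items()})
        ).iloc[0]
        assert scaled_non_std["total_fa_vs_c19"] == pytest.approx(c * base["total_fa_vs_c19"], rel=1e-9)
        assert scaled_non_std["scd1_ratio"] == pytest.approx(base["scd1_ratio"], rel=1e-9)


class TestTgPlRatio:
    def test_equal_totals_give_unity(self):
        t = pd.concat(
            [_table({"C16:0": 30.0, "C18:0": 30.0}, fraction="TG"),
             _table({"C16:0": 20.0, "C18:0": 40.0}, fraction="PL")],
            ignore_index=True,
        )
        assert am.tg_pl_ratio(t).iloc[0]["tg_pl_ratio"] == pytest.approx(1.0)

    def test_three_to_one(self):
        t = pd.concat(
            [_table({"C16:0": 60.0, "C19:0": 5.0}, fraction="TG"),
             _table({"C16:0": 20.0, "C19:0": 5.0}, fraction="PL")],
            ignore_index=True,
        )
        assert am.tg_pl_ratio(t).iloc[0]["tg_pl_ratio"] == pytest.approx(3.0)

    def test_generator_fraction_scale_recovered_exactly(self):
        params = am.FAGroupParams(
            concentration=None, effect_multipliers={}, total_fa_scale={},
            fraction_scale={"TG": 40.0, "PL": 20.0}, seed=0,
        )
        ratios = am.tg_pl_ratio(am.generate_fa_tables(params))
        assert np.allclose(ratios["tg_pl_ratio"], 2.0)

    def test_missing_fraction_flagged(self):
        t = _table({"C16:0": 60.0}, fraction="TG")
        with pytest.warns(UserWarning, match="missing TG or PL"):
            out = am.tg_pl_ratio(t)
        assert np.isnan(out.iloc[0]["tg_pl_ratio"])
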