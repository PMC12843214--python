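import hashlib

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alveomech.cbct import (MeasurementTable, PairedMeasurements, TableError,
                            read_table, compute_changes, dahlberg_error, icc,
                            load_fixture, fixture_path, round_half_up)

# sha256 of the shipped transcriptions — guards against accidental edits
FIXTURE_SHA256 = {
    "table3_maxilla.csv":
        "0472570430e073bf5c4cfe61e20f7d9e485b6b66cc0811cbdb2afce38a6dc357",
    "table3_mandible.csv":
        "0babe0fb8f0128561e8553ae099b35c400dce2fb7eb10444ffd33c0877293204",
    "table4_buccal_plate.csv":
        "71cee8ab6af17cb91ea3ea584dd0682040eb878f0d4909f132d80b862921e593",
}


class TestFixtures:
    def test_transcription_checksums(self):
        for name, want in FIXTURE_SHA256.items():
            got = hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()
            assert got == want, f"fixture {name} changed"

    @pytest.mark.parametrize("site,arch,n", [
        ("ridge_width", "maxilla", 11),
        ("ridge_width", "mandible", 12),
        ("buccal_plate", "none", 16),
    ])
    def test_row_counts(self, site, arch, n):
        assert len(load_fixture(site, arch)) == n


class TestReadTable:
    def test_unicode_minus_normalized(self, tmp_path):
        from alveomech.cbct import _parse_number
        assert _parse_number("−0.07", 2, "delta") == -0.07
        # and through the reader: U+2212 zero is a valid non-negative value
        f = tmp_path / "t.csv"
        f.write_text("segment,pre_mm,post_mm\n1,−0.00,0.07\n",
                     encoding="utf-8")
        t = read_table(f, "buccal_plate")
        assert t.rows.pre_mm.iloc[0] == 0.0

    def test_missing_column(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("segment,pre_mm\n1,1.0\n")
        with pytest.raises(TableError, match="post_mm"):
            read_table(f, "ridge_width")

    def test_non_numeric_names_row(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("segment,pre_mm,post_mm\n1,1.0,2.0\n2,abc,2.0\n")
        with pytest.raises(TableError, match="row 3"):
            read_table(f, "ridge_width")

    def test_duplicate_segment(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("segment,pre_mm,post_mm\n1,1.0,2.0\n1,1.5,2.0\n")
        with pytest.raises(TableError, match="duplicate"):
            read_table(f, "ridge_width")


class TestComputeChanges:
    def test_known_rows(self):
        maxilla = compute_changes(load_fixture("ridge_width", "maxilla"))
        row6 = maxilla.rows.set_index("segment").loc["6"]
        assert row6.pre_mm == 7.60 and row6.post_mm == 8.56
        assert row6.delta_reported == pytest.approx(0.96)
        plate = compute_changes(load_fixture("buccal_plate"))
        row4 = plate.rows.set_index("segment").loc["4"]
        assert row4.delta_reported == pytest.approx(0.67)

    def test_summary_consistent(self):
        ch = compute_changes(load_fixture("ridge_width", "mandible"))
        s = ch.summary
        assert s["n"] == 12
        assert s["n_positive"] + s["n_negative"] + s["n_zero"] == 12
        assert s["n_zero"] == 1                 # one segment with no change
        assert s["mean_delta_mm"] == pytest.approx(ch.rows.delta_mm.mean())

    def test_zero_delta_counted(self):
        import pandas as pd
        t = MeasurementTable("ridge_width", "none", pd.DataFrame(
            {"segment": ["a"], "pre_mm": [2.0], "post_mm": [2.0]}))
        ch = compute_changes(t)
        assert ch.summary["n_zero"] == 1

    def test_empty_rejected(self):
        import pandas as pd
        t = MeasurementTable("ridge_width", "none", pd.DataFrame(
            columns=["segment", "pre_mm", "post_mm"]))
        with pytest.raises(TableError, match="empty"):
            compute_changes(t)

    def test_rounding_half_up(self):
        assert round_half_up(0.125) == 0.13
        assert round_half_up(-0.125) == -0.13
        assert round_half_up(0.964999) == 0.96


class TestDahlberg:
    def test_identical_pairs_zero(self):
        p = PairedMeasurements(["a", "b"], [1.0, 2.0], [1.0, 2.0])
        assert dahlberg_error(p) == 0.0

    def test_single_pair_closed_form(self):
        p = PairedMeasurements(["a"], [1.0], [2.0])
        assert dahlberg_error(p) == pytest.approx(np.sqrt(0.5))

    def test_monte_carlo_recovers_noise_sd(self):
        rng = np.random.default_rng(42)
        true = rng.normal(8.0, 1.0, 1000)
        p = PairedMeasurements([str(i) for i in range(1000)],
                               true + rng.normal(0, 0.1, 1000),
                               true + rng.normal(0, 0.1, 1000))
        assert 0.09 < dahlberg_error(p) < 0.11

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
                    min_size=1, max_size=20),
           st.floats(-5, 5))
    def test_swap_and_shift_invariance(self, pairs, shift):
        m1 = np.array([a for a, _ in pairs])
        m2 = np.array([b for _, b in pairs])
        labels = [str(i) for i in range(len(pairs))]
        base = dahlberg_error(PairedMeasurements(labels, m1, m2))
        swapped = dahlberg_error(PairedMeasurements(labels, m2, m1))
        shifted = dahlberg_error(PairedMeasurements(labels, m1 + shift,
                                                    m2 + shift))
        assert swapped == base
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestICC:
    def test_perfect_agreement(self):
        p = PairedMeasurements(list("abcd"), [1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert icc(p) == pytest.approx(1.0)

    def test_requires_three_pairs(self):
        with pytest.raises(TableError):
            icc(PairedMeasurements(["a", "b"], [1, 2.0], [1, 2.0]))

    def test_zero_variance_undefined(self):
        with pytest.raises(TableError, match="zero total variance"):
            icc(PairedMeasurements(list("abc"), [1, 1, 1.0], [1, 1, 1.0]))

    def test_recovers_variance_ratio(self):
        rng = np.random.default_rng(7)
        n = 2000
        subj = rng.normal(0, 1.0, n)
        p = PairedMeasurements([str(i) for i in range(n)],
                               subj + rng.normal(0, 1.0, n),
                               subj + rng.normal(0, 1.0, n))
        assert icc(p) == pytest.approx(0.5, abs=0.02)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(11)
        n = 2000
        p = PairedMeasurements([str(i) for i in range(n)],
                               rng.normal(0, 1.0, n), rng.normal(0, 1.0, n))
        assert abs(icc(p)) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        subj = rng.normal(5, 1.0, 50)
        m1 = subj + rng.normal(0, 0.3, 50)
        m2 = subj + rng.normal(0, 0.3, 50)
        labels = [str(i) for i in range(50)]
        a = icc(PairedMeasurements(labels, m1, m2))
        b = icc(PairedMeasurements(labels, 3.0 * m1 + 10, 3.0 * m2 + 10))
        assert b == pytest.approx(a, rel=1e-12)

    def test_against_pingouin(self):
        """Independent cross-check: two-way random, absolute agreement,
        single measurement (ICC2 in pingouin's nomenclature)."""
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(19)
        n = 40
        subj = rng.normal(8, 1.2, n)
        bias = 0.15                           # rater systematic difference
        m1 = subj + rng.normal(0, 0.3, n)
        m2 = subj + bias + rng.normal(0, 0.3, n)
        ours = icc(PairedMeasurements([str(i) for i in range(n)], m1, m2))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile(["r1", "r2"], n),
            "score": np.column_stack([m1, m2]).ravel(),
        })
        res = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        ref = float(res.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert ours == pytest.approx(ref, abs=1e-10)
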