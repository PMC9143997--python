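"""Quenching-analysis formulas: worked values, errors and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamdsi import fluorpar as fp
from pamdsi.synthgen import AOIMeasurement


@pytest.mark.parametrize(
    "f0, fm, expected",
    [
        (0.2, 1.0, 0.8),
        (0.5, 0.5, 0.0),            # boundary: f0 = fm
        (0.18, 1.0, 0.82),          # the unstressed-leaf reference value
    ],
)
def test_fv_fm_values(f0, fm, expected):
    assert fp.fv_fm(f0, fm) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("f0, fm", [(1.2, 1.0), (0.0, 1.0), (-0.1, 1.0), (0.2, 0.0)])
def test_fv_fm_rejects_invalid(f0, fm):
    with pytest.raises(ValueError):
        fp.fv_fm(f0, fm)


class TestFoPrime:
    def test_no_quenching_limit(self):
        # Fm' = Fm means no quenching has developed, so Fo' = F0 exactly
        assert fp.estimate_fo_prime(0.2, 1.0, 1.0) == pytest.approx(0.2, abs=1e-15)

    def test_worked_value(self):
        # 0.2 / (0.8 + 0.2/0.5) = 0.2 / 1.2
        assert fp.estimate_fo_prime(0.2, 1.0, 0.5) == pytest.approx(1 / 6, abs=1e-9)

    def test_monotone_in_fm_prime(self):
        vals = [fp.estimate_fo_prime(0.2, 1.0, fmp) for fmp in (1.0, 0.8, 0.6, 0.4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(v <= 0.2 + 1e-12 for v in vals)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fp.estimate_fo_prime(0.2, 1.0, 1.2)


class TestYields:
    def test_worked_value(self):
        yii, ynpq, yno = fp.yields(0.4, 0.5, 1.0)
        assert (yii, ynpq, yno) == pytest.approx((0.2, 0.4, 0.4), abs=1e-12)

    def test_fully_closed_no_quenching(self):
        assert fp.yields(1.0, 1.0, 1.0) == pytest.approx((0.0, 0.0, 1.0), abs=1e-15)

    def test_rejects_ordering_violation(self):
        with pytest.raises(ValueError):
            fp.yields(0.6, 0.5, 1.0)
        with pytest.raises(ValueError):
            fp.yields(0.4, 1.1, 1.0)


class TestQuenching:
    def test_worked_values(self):
        qp, ql, qn, npq = fp.quenching(0.4, 0.5, 0.25, 1.0, 0.2)
        assert qp == pytest.approx(0.4, abs=1e-12)
        assert ql == pytest.approx(0.25, abs=1e-12)
        assert qn == pytest.approx(0.6875, abs=1e-12)
        assert npq == pytest.approx(1.0, abs=1e-12)

    def test_dark_state_identity(self):
        qp, ql, qn, npq = fp.quenching(0.2, 1.0, 0.2, 1.0, 0.2)
        assert (qp, qn, npq) == pytest.approx((1.0, 0.0, 0.0), abs=1e-12)

    def test_all_centers_closed(self):
        qp, ql, qn, npq = fp.quenching(0.5, 0.5, 0.25, 1.0, 0.2)
        assert qp == 0.0 and ql == 0.0

    def test_rejects_fo_prime_above_fm_prime(self):
        with pytest.raises(ValueError):
            fp.quenching(0.4, 0.5, 0.6, 1.0, 0.2)


@pytest.mark.parametrize(
    "yii, par, expected",
    [(0.2, 300.0, 25.2), (0.7, 0.0, 0.0), (0.14, 300.0, 17.64)],
)
def test_etr_values(yii, par, expected):
    assert fp.etr(yii, par) == pytest.approx(expected, abs=1e-12)


def test_etr_bilinear():
    assert fp.etr(0.4, 150.0) == pytest.approx(2 * fp.etr(0.2, 150.0))
    assert fp.etr(0.2, 300.0) == pytest.approx(2 * fp.etr(0.2, 150.0))


valid_reading = st.tuples(
    st.floats(0.05, 50.0),    # fm
    st.floats(0.02, 0.98),    # fm_prime / fm
    st.floats(0.02, 0.98),    # fs / fm_prime
    st.floats(0.02, 0.95),    # f0 / fm
).map(lambda t: (t[0] * t[2] * t[1], t[0] * t[1], t[0] * t[3], t[0]))
# -> (fs, fm_prime, f0, fm) with 0 < fs <= fm' <= fm and 0 < f0 < fm


@settings(max_examples=300, derandomize=True)
@given(valid_reading)
def test_yield_partition_sums_to_one(reading):
    fs, fm_prime, _, fm = reading
    yii, ynpq, yno = fp.yields(fs, fm_prime, fm)
    assert abs(yii + ynpq + yno - 1.0) < 5e-15
    assert 0 <= yii <= 1 and -1e-15 <= ynpq <= 1 and 0 <= yno <= 1


@pytest.mark.filterwarnings("ignore:qP outside")
@settings(max_examples=200, derandomize=True)
@given(valid_reading, st.floats(0.01, 100.0))
def test_dimensionless_parameters_scale_invariant(reading, c):
    fs, fm_prime, f0, fm = reading
    fop = fp.estimate_fo_prime(f0, fm, fm_prime)
    base = (
        fp.fv_fm(f0, fm),
        *fp.yields(fs, fm_prime, fm),
        *fp.quenching(fs, fm_prime, fop, fm, f0),
    )
    fop_c = fp.estimate_fo_prime(c * f0, c * fm, c * fm_prime)
    scaled = (
        fp.fv_fm(c * f0, c * fm),
        *fp.yields(c * fs, c * fm_prime, c * fm),
        *fp.quenching(c * fs, c * fm_prime, fop_c, c * fm, c * f0),
    )
    assert np.allclose(base, scaled, rtol=1e-9, atol=1e-9)


@pytest.mark.filterwarnings("ignore:qP outside")
@settings(max_examples=300, derandomize=True)
@given(valid_reading)
def test_qn_bounded_with_estimated_fo_prime(reading):
    # the Oxborough-Baker Fo' keeps the classical qN coefficient in [0, 1]
    fs, fm_prime, f0, fm = reading
    fop = fp.estimate_fo_prime(f0, fm, fm_prime)
    _, _, qn, _ = fp.quenching(fs, fm_prime, fop, fm, f0)
    assert -1e-12 <= qn <= 1 + 1e-12


def _measurement_from_targets(f0, fm, par, yii, npq):
    """Invert target yields/NPQ into raw readings (the generator's trick)."""
    steps = []
    for p, y, q in zip(par, yii, npq):
        fm_prime = fm / (1 + q)
        steps.append((p, fm_prime * (1 - y), fm_prime))
    return AOIMeasurement(keys={"aoi": 1}, f0=f0, fm=fm, steps=steps)


class TestComputeAll:
    def test_roundtrip_recovers_known_yields(self):
        par = [0.0, 100.0, 300.0]
        yii = [0.8, 0.4, 0.2]
        npq = [0.0, 0.3, 0.9]
        m = _measurement_from_targets(0.2, 1.0, par, yii, npq)
        rec = fp.compute_all(m)
        assert rec.yii == pytest.approx(yii, abs=1e-12)
        assert rec.npq == pytest.approx(npq, abs=1e-12)
        assert rec.etr == pytest.approx([0.0, 0.4 * 42.0, 0.2 * 126.0], abs=1e-9)

    def test_thirteen_steps(self, tiny_run):
        from pamdsi.synthgen import measurements_to_aoi_records

        sub = tiny_run["measurements"].query("genotype == 'G000' and block == 1")
        rec = fp.compute_all(measurements_to_aoi_records(sub)[0])
        assert rec.n_steps == 13

    def test_invariants_on_simulated_records(self, tiny_run):
        fl = tiny_run["fluor"]
        assert ((fl.yii >= 0) & (fl.yii <= 1)).all()
        assert ((fl.qp >= 0) & (fl.qp <= 1)).all()
        assert ((fl.ql >= 0) & (fl.ql <= 1)).all()
        assert (fl.npq >= 0).all()
        assert (fl.etr >= 0).all()
        assert (fl.loc[fl.par == 0, "etr"] == 0).all()
        assert np.abs(fl.yii + fl.ynpq + fl.yno - 1).max() < 5e-15

    def test_error_carries_aoi_context(self):
        m = _measurement_from_targets(0.2, 1.0, [0.0, 100.0], [0.5, 0.4], [0.0, 0.2])
        m.steps[1] = (100.0, 1.5, 0.8)  # fs > fm'
        with pytest.raises(ValueError, match="aoi"):
            fp.compute_all(m)


def test_compute_table_matches_scalar_path(tiny_run):
    from pamdsi.synthgen import measurements_to_aoi_records

    sub = tiny_run["measurements"].query(
        "genotype == 'G002' and block == 2 and plant == 1 and leaf == 1"
        " and leaflet == 1 and aoi == 1"
    )
    table = fp.compute_table(sub)
    for cond in ("healthy", "infected"):
        part = sub[sub.condition == cond]
        rec = fp.compute_all(measurements_to_aoi_records(part)[0])
        got = table[table.condition == cond].sort_values("par")
        assert got["yii"].to_numpy() == pytest.approx(rec.yii, rel=1e-12)
        assert got["qn"].to_numpy() == pytest.approx(rec.qn, rel=1e-12)
        assert got["etr"].to_numpy() == pytest.approx(rec.etr, rel=1e-12)
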