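"""Single dynamic-microtubule simulator: contracts and dynamics."""

import numpy as np
import pytest

from neuritesim import DomainError, SingleMTParams, simulate_single_mt, summarize_trace
from neuritesim.mt_single import DIMER_LENGTH_UM, LengthTrace


def _params(tu=9.0, h=0.72, **kw):
    return SingleMTParams(tubulin_conc=tu, hydrolysis_rate=h, **kw)


class TestSimulateContract:
    def test_seed_determinism(self):
        """Identical seeds give identical traces; different seeds differ."""
        a = simulate_single_mt(_params(), 2000.0, seed=42)
        b = simulate_single_mt(_params(), 2000.0, seed=42)
        c = simulate_single_mt(_params(), 2000.0, seed=43)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.lengths, b.lengths)
        assert not np.array_equal(a.lengths[: len(c.lengths)], c.lengths[: len(a.lengths)])

    def test_trace_invariants(self):
        tr = simulate_single_mt(_params(), 5000.0, seed=7)
        assert np.all(np.diff(tr.times) > 0)
        assert np.all(tr.lengths >= 0)
        assert tr.times[-1] == pytest.approx(5000.0)

    def test_zero_hydrolysis_grows_monotonically(self):
        """Without GTP hydrolysis the cap never collapses: no catastrophe,
        essentially monotone net growth and zero degradation rate."""
        tr = simulate_single_mt(_params(h=0.0), 5000.0, seed=3)
        mean_um, k_deg = summarize_trace(tr)
        assert k_deg == 0.0
        # net growth dominates: final length close to (a-b)*t
        assert tr.lengths[-1] > 0.5 * (9.0 * 0.9 - 0.9) * 5000.0

    @pytest.mark.parametrize(
        "kwargs", [{"duration": -1.0}, {"duration": 0.0}]
    )
    def test_bad_duration_rejected(self, kwargs):
        with pytest.raises(DomainError):
            simulate_single_mt(_params(), seed=1, **kwargs)

    def test_negative_rates_rejected(self):
        with pytest.raises(DomainError):
            SingleMTParams(tubulin_conc=-1.0, hydrolysis_rate=0.7)
        with pytest.raises(DomainError):
            SingleMTParams(tubulin_conc=9.0, hydrolysis_rate=-0.1)

    def test_dynamic_instability_regime(self):
        """At (9 uM, 0.72/s) the trace alternates growth and breakdown:
        it reaches um-scale lengths and suffers complete breakdowns."""
        tr = simulate_single_mt(_params(), 26_000.0, seed=11)
        mean_um, k_deg = summarize_trace(tr)
        assert tr.lengths.max() * DIMER_LENGTH_UM > 1.0
        assert k_deg > 0.0
        assert 0.5 < mean_um < 20.0


class TestSummarize:
    def test_constant_trace(self):
        tr = LengthTrace(
            times=np.array([0.0, 100.0, 200.0]),
            lengths=np.array([100, 100, 100]),
            seed=0,
        )
        mean_um, k_deg = summarize_trace(tr, breakdown_threshold=4)
        assert mean_um == pytest.approx(100 * DIMER_LENGTH_UM)
        assert k_deg == 0.0

    def test_crossing_count_definition(self):
        """13 downward threshold crossings in 26,000 s -> 0.03/min."""
        times, lengths = [0.0], [50]
        t = 0.0
        for _ in range(13):
            t += 1000.0
            times += [t, t + 1.0]
            lengths += [0, 50]
        times.append(26_000.0)
        lengths.append(50)
        tr = LengthTrace(times=np.array(times), lengths=np.array(lengths), seed=0)
        _, k_deg = summarize_trace(tr, breakdown_threshold=4)
        assert k_deg == pytest.approx(13 / (26_000 / 60))

    def test_mean_excludes_subthreshold_intervals(self):
        tr = LengthTrace(
            times=np.array([0.0, 10.0, 20.0, 30.0]),
            lengths=np.array([100, 0, 100, 100]),
            seed=0,
        )
        mean_um, _ = summarize_trace(tr, breakdown_threshold=4)
        assert mean_um == pytest.approx(100 * DIMER_LENGTH_UM)

    def test_empty_trace_rejected(self):
        tr = LengthTrace(times=np.array([]), lengths=np.array([]), seed=0)
        with pytest.raises(DomainError):
            summarize_trace(tr)


class TestHydrolysisEffect:
    def test_higher_hydrolysis_shortens_and_destabilises(self):
        """Replicate comparison at (9 uM, 0.675/s) vs (9 uM, 0.72/s):
        faster GTP hydrolysis gives shorter filaments and more frequent
        complete breakdowns."""
        means, degs = {}, {}
        for h in (0.675, 0.72):
            m, d = [], []
            for s in range(20):
                tr = simulate_single_mt(_params(h=h), 26_000.0, seed=100 + s)
                mu, kd = summarize_trace(tr)
                m.append(mu)
                d.append(kd)
            means[h], degs[h] = np.mean(m), np.mean(d)
        assert means[0.675] > means[0.72]
        assert degs[0.675] < degs[0.72]

    def test_statistical_reproducibility(self):
        """Batch means of (mean length, degradation rate) are stable:
        relative SD across 5 batches of 10 replicates stays below 10%."""
        mus, kds = [], []
        for s in range(50):
            tr = simulate_single_mt(_params(), 26_000.0, seed=500 + s)
            mu, kd = summarize_trace(tr)
            mus.append(mu)
            kds.append(kd)
        for values in (mus, kds):
            batches = np.asarray(values).reshape(5, 10).mean(axis=1)
            assert batches.std() / batches.mean() < 0.10
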