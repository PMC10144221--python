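"""Event IO, gating, and viability quantification."""

import math

import numpy as np
import pandas as pd
import pytest

from printability.cytometry import (
    EventTable,
    GatingConfig,
    derive_dead_threshold,
    gate,
    read_events,
    viability,
    write_fcs,
)
from printability.synthetic import simulate_cytometry


@pytest.fixture(scope="module")
def mixed_sample():
    return simulate_cytometry(
        10_000, viability=0.9, debris_fraction=0.2, agglomerate_fraction=0.0, seed=11
    )


@pytest.fixture(scope="module")
def dead_control():
    table, _ = simulate_cytometry(
        5_000, viability=0.0, debris_fraction=0.0, agglomerate_fraction=0.0, seed=12
    )
    return table


class TestIO:
    def test_csv_roundtrip(self, tmp_path, mixed_sample):
        table, _ = mixed_sample
        p = tmp_path / "events.csv"
        table.data.to_csv(p, index=False)
        back = read_events(p)
        assert len(back) == len(table)
        assert np.allclose(back.data["green"], table.data["green"])

    def test_fcs_matches_csv_twin(self, tmp_path, mixed_sample):
        table, _ = mixed_sample
        fcs = tmp_path / "events.fcs"
        csv = tmp_path / "events.csv"
        write_fcs(fcs, table)
        table.data.to_csv(csv, index=False)
        a = read_events(fcs)
        b = read_events(csv)
        assert np.allclose(a.data.to_numpy(), b.data.to_numpy(), rtol=1e-6)

    def test_missing_channel_raises(self, tmp_path):
        p = tmp_path / "nored.csv"
        pd.DataFrame({"fsc": [1.0, 2.0], "ssc": [1.0, 2.0], "green": [1.0, 2.0]}).to_csv(
            p, index=False
        )
        with pytest.raises(ValueError, match="channel not found"):
            read_events(p)

    def test_instrument_channel_names_mapped(self, tmp_path):
        p = tmp_path / "inst.csv"
        pd.DataFrame(
            {"FSC-A": [1e4] * 3, "SSC-A": [1e4] * 3, "FITC-A": [5e3] * 3, "PE-A": [10.0] * 3}
        ).to_csv(p, index=False)
        assert len(read_events(p)) == 3

    def test_malformed_fcs_raises(self, tmp_path):
        p = tmp_path / "bad.fcs"
        p.write_bytes(b"not an fcs file at all")
        with pytest.raises(ValueError, match="parse error"):
            read_events(p)


class TestDeadThreshold:
    def test_quantile_threshold_classifies_control_dead(self, dead_control):
        thr = derive_dead_threshold(dead_control, quantile=0.01)
        cfg = GatingConfig(red_threshold=thr)
        gated = gate(dead_control, cfg)
        assert (gated.data["label"] == "dead").mean() >= 0.99

    def test_threshold_below_uniform_control(self):
        data = pd.DataFrame(
            {"fsc": [5e4] * 200, "ssc": [3e4] * 200, "green": [10.0] * 200, "red": [1000.0] * 200}
        )
        thr = derive_dead_threshold(EventTable(data=data), config=GatingConfig())
        assert thr <= 1000.0

    def test_zero_quantile_is_control_minimum(self, dead_control):
        cfg = GatingConfig()
        thr = derive_dead_threshold(dead_control, quantile=0.0, config=cfg)
        d = dead_control.data
        inside = d["fsc"].between(*cfg.fsc_bounds) & d["ssc"].between(*cfg.ssc_bounds)
        assert thr == pytest.approx(float(d.loc[inside, "red"].min()), rel=1e-9)

    def test_small_control_rejected(self):
        data = pd.DataFrame({c: np.ones(10) for c in ("fsc", "ssc", "green", "red")})
        with pytest.raises(ValueError, match="insufficient control"):
            derive_dead_threshold(EventTable(data=data))


class TestGating:
    def test_classification_accuracy_on_separated_clusters(self, mixed_sample):
        table, truth = mixed_sample
        gated = gate(table, GatingConfig())
        labels = np.asarray(truth.labels)[gated.data.index]
        cells = np.isin(labels, ["live", "dead"])
        acc = (gated.data["label"].to_numpy()[cells] == labels[cells]).mean()
        assert acc >= 0.99

    def test_debris_exclusion_fraction(self, mixed_sample):
        table, truth = mixed_sample
        gated = gate(table, GatingConfig())
        assert abs(gated.fraction_excluded - truth.debris_fraction) <= 0.03

    def test_everything_excluded_raises(self, mixed_sample):
        table, _ = mixed_sample
        cfg = GatingConfig(fsc_bounds=(1e9, 2e9))
        with pytest.raises(ValueError, match="all events excluded"):
            gate(table, cfg)

    def test_gate_order_independence(self, mixed_sample):
        # scatter gate then classify == classify all then restrict to the gate
        table, _ = mixed_sample
        cfg = GatingConfig()
        gated = gate(table, cfg)
        wide = GatingConfig(fsc_bounds=(1e-9, 1e12), ssc_bounds=(1e-9, 1e12),
                            green_threshold=cfg.green_threshold,
                            red_threshold=cfg.red_threshold)
        all_classified = gate(table, wide).data
        restricted = all_classified.loc[gated.data.index, "label"]
        assert (restricted == gated.data["label"]).all()

    def test_monotone_channel_rescaling_preserves_viability(self, mixed_sample):
        table, _ = mixed_sample
        cfg = GatingConfig()
        v0 = viability(gate(table, cfg))
        scaled = EventTable(data=table.data.assign(green=table.data["green"] * 7.0))
        cfg2 = GatingConfig(fsc_bounds=cfg.fsc_bounds, ssc_bounds=cfg.ssc_bounds,
                            green_threshold=cfg.green_threshold * 7.0,
                            red_threshold=cfg.red_threshold)
        v1 = viability(gate(scaled, cfg2))
        assert v1.viability == v0.viability
        assert v1.n_live == v0.n_live


class TestViability:
    def test_direct_ratio(self):
        data = pd.DataFrame(
            {
                "fsc": np.full(10_000, 5e4),
                "ssc": np.full(10_000, 3e4),
                "green": np.r_[np.full(9_630, 1e4), np.full(370, 10.0)],
                "red": np.r_[np.full(9_630, 10.0), np.full(370, 1e4)],
            }
        )
        res = viability(gate(EventTable(data=data), GatingConfig()))
        assert res.n_live == 9_630
        assert res.n_dead == 370
        assert res.viability == pytest.approx(0.963)

    def test_all_live_is_unity(self):
        table, _ = simulate_cytometry(1_000, viability=1.0, debris_fraction=0.0,
                                      agglomerate_fraction=0.0, seed=13)
        assert viability(gate(table, GatingConfig())).viability == 1.0

    def test_recovery_within_binomial_error(self):
        n, true_v = 5_000, 0.664
        table, _ = simulate_cytometry(n, viability=true_v, debris_fraction=0.05,
                                      agglomerate_fraction=0.0, seed=14)
        res = viability(gate(table, GatingConfig()))
        se = math.sqrt(true_v * (1 - true_v) / (res.n_live + res.n_dead))
        assert abs(res.viability - true_v) <= 3 * se

    def test_estimator_recovery_and_interval_coverage(self):
        # 200 simulated samples over a viability grid: small bias, good coverage
        grid = np.linspace(0.5, 1.0, 200)
        errs, covered = [], 0
        cfg = GatingConfig()
        for i, v in enumerate(grid):
            table, _ = simulate_cytometry(5_000, viability=float(v), debris_fraction=0.05,
                                          agglomerate_fraction=0.01, seed=1000 + i)
            res = viability(gate(table, cfg))
            n = res.n_live + res.n_dead
            errs.append(res.viability - v)
            half = 1.96 * math.sqrt(max(res.viability * (1 - res.viability), 1e-12) / n)
            if abs(res.viability - v) <= half + 1e-12:
                covered += 1
        assert np.mean(np.abs(errs)) < 0.01
        assert covered / len(grid) >= 0.90

    def test_no_cells_after_gating(self):
        data = pd.DataFrame(
            {"fsc": [5e4] * 5, "ssc": [3e4] * 5, "green": [10.0] * 5, "red": [10.0] * 5}
        )
        with pytest.raises(ValueError, match="no cells after gating"):
            viability(gate(EventTable(data=data), GatingConfig()))
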