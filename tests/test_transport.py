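"""Well-level permeability, efflux-ratio and QC arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbbflux.errors import InvalidInputError, UndefinedEffluxError
from bbbflux.transport import (
    QCSettings,
    TransportWell,
    apply_qc,
    build_efflux_table,
    compute_er,
    compute_papp,
    compute_recovery,
    compute_ref,
    net_er,
    total_er,
    total_er_ref,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestPapp:
    def test_hand_arithmetic(self):
        # 0.792 pmol over 120 min across 0.11 cm2 at 1 uM -> 1e-6 cm/s
        assert compute_papp(0.792, 1.0, 120.0, 0.11) == pytest.approx(1e-6)
        assert compute_papp(7.92, 1.0, 120.0, 0.11) == pytest.approx(1e-5)

    def test_no_transport_gives_zero(self):
        assert compute_papp(0.0, 1.0, 120.0, 0.11) == 0.0

    @pytest.mark.parametrize("kwargs", [
        {"c0_donor_um": 0.0}, {"t_end_min": -1.0}, {"filter_area_cm2": 0.0},
    ])
    def test_invalid_inputs(self, kwargs):
        base = {"amount_receiver_pmol": 1.0, "c0_donor_um": 1.0,
                "t_end_min": 120.0, "filter_area_cm2": 0.11}
        with pytest.raises(InvalidInputError):
            compute_papp(**{**base, **kwargs})

    @given(q=positive, c0=positive, t=positive, a=positive, k=st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True)
    def test_scaling_laws(self, q, c0, t, a, k):
        """Linear in receiver amount, inverse-linear in t, A and C0."""
        base = compute_papp(q, c0, t, a)
        assert compute_papp(k * q, c0, t, a) == pytest.approx(k * base, rel=1e-9)
        assert compute_papp(q, k * c0, t, a) == pytest.approx(base / k, rel=1e-9)
        assert compute_papp(q, c0, k * t, a) == pytest.approx(base / k, rel=1e-9)
        # doubling dose and receiver amount together leaves P_app unchanged
        assert compute_papp(2 * q, 2 * c0, t, a) == pytest.approx(base, rel=1e-9)


class TestRecovery:
    def test_full_mass_balance(self):
        assert compute_recovery(20.0, 80.0, 100.0) == pytest.approx(100.0)

    def test_low_recovery_fails_threshold(self):
        rec = compute_recovery(10.0, 45.0, 100.0)
        assert rec == pytest.approx(55.0)
        assert rec < QCSettings().recovery_limit_pct

    def test_boundary_is_retained(self):
        rec = compute_recovery(0.0, 60.0, 100.0)
        assert rec == pytest.approx(60.0)
        assert not rec < QCSettings().recovery_limit_pct

    def test_zero_dose_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_recovery(1.0, 1.0, 0.0)


class TestEffluxRatios:
    def test_er_hand_arithmetic(self):
        assert compute_er(1e-6, 2e-5) == pytest.approx(20.0)
        assert compute_er(3e-6, 3e-6) == pytest.approx(1.0)

    def test_er_undefined_for_zero_ab(self):
        with pytest.raises(UndefinedEffluxError):
            compute_er(0.0, 1e-6)

    def test_net_er_examples(self):
        assert net_er(17.7, 1.2) == pytest.approx(16.5)
        assert net_er(2.0, 2.0) == 0.0
        assert net_er(1.5, 2.0) == 0.0  # floored, never negative

    @pytest.mark.parametrize("m,b,expected", [(0, 0, 1), (5, 2, 8), (16.5, 0, 17.5)])
    def test_total_er(self, m, b, expected):
        assert total_er(m, b) == pytest.approx(expected)

    @pytest.mark.parametrize("brain,cell,expected", [(4.0, 40.0, 0.1), (5.0, 5.0, 1.0), (6.0, 20.0, 0.3)])
    def test_ref(self, brain, cell, expected):
        assert compute_ref(brain, cell) == pytest.approx(expected)

    def test_total_er_ref_examples(self):
        assert total_er_ref(10, 0, 0.1, 0.2) == pytest.approx(2.0)
        assert total_er_ref(0, 0, 0.5, 0.7) == pytest.approx(1.0)

    @given(m=st.floats(0, 50), b=st.floats(0, 50))
    @settings(max_examples=50, derandomize=True)
    def test_unit_refs_reduce_to_total_er(self, m, b):
        assert total_er_ref(m, b, 1.0, 1.0) == pytest.approx(total_er(m, b))

    @given(m=st.floats(0, 50), b=st.floats(0, 50), dm=st.floats(0, 10),
           r1=st.floats(0.01, 5), r2=st.floats(0.01, 5))
    @settings(max_examples=50, derandomize=True)
    def test_total_er_monotone_in_net_er(self, m, b, dm, r1, r2):
        assert total_er(m + dm, b) >= total_er(m, b)
        assert total_er_ref(m + dm, b, r1, r2) >= total_er_ref(m, b, r1, r2)


class TestWellInvariants:
    def test_mass_balance_enforced(self):
        with pytest.raises(InvalidInputError):
            TransportWell(
                compound_id="X", cell_line="hMDR1", direction="A2B",
                inhibitor_arm="vehicle", c0_donor=1.0, t_end=120.0,
                amount_receiver_end=200.0, amount_donor_end=200.0,
            )  # 400 pmol recovered from a 250 pmol dose

    def test_dose_property(self):
        w = TransportWell(
            compound_id="X", cell_line="hMDR1", direction="A2B",
            inhibitor_arm="vehicle", c0_donor=1.0, t_end=120.0,
            amount_receiver_end=5.0, amount_donor_end=200.0,
        )
        assert w.dose_pmol == pytest.approx(250.0)


def _well_row(cid, line, recv, donor, **over):
    row = {
        "compound_id": cid, "cell_line": line, "direction": "A2B",
        "inhibitor_arm": "vehicle", "c0_donor_uM": 1.0, "t_end_min": 120.0,
        "amount_receiver_pmol": recv, "amount_donor_pmol": donor,
        "receiver_volume_mL": 0.25, "donor_volume_mL": 0.25,
        "filter_area_cm2": 0.11, "replicate_id": 0,
    }
    row.update(over)
    return row


class TestApplyQC:
    def test_ly_rejection_is_strictly_greater(self):
        wells = pd.DataFrame([_well_row("A", "hMDR1", 5, 240), _well_row("B", "hMDR1", 5, 240)])
        ly = pd.DataFrame(
            {
                "compound_id": ["A", "B"],
                "cell_line": ["hMDR1", "hMDR1"],
                "ly_papp_cm_per_s": [2.5e-6, 2.0e-6],  # B sits exactly on the limit
            }
        )
        kept, log = apply_qc(wells, ly)
        assert set(kept["compound_id"]) == {"B"}
        assert log[0]["reason"] == "ly_papp_above_limit"
        assert log[0]["compound_id"] == "A"

    def test_recovery_exclusion_boundary(self):
        wells = pd.DataFrame(
            [
                _well_row("LOW", "hMDR1", 5.0, 144.75),   # 59.9% of 250 pmol
                _well_row("EDGE", "hMDR1", 5.0, 145.0),   # exactly 60%
            ]
        )
        kept, log = apply_qc(wells, None)
        assert set(kept["compound_id"]) == {"EDGE"}
        assert log[0]["reason"] == "recovery_below_limit"
        assert log[0]["value"] == pytest.approx(59.9)

    def test_log_partitions_input_exactly(self):
        wells = pd.DataFrame(
            [_well_row("A", "hMDR1", 5, 240), _well_row("B", "hMDR1", 5, 50),
             _well_row("C", "rMDR1", 5, 240)]
        )
        ly = pd.DataFrame({"compound_id": ["C"], "cell_line": ["rMDR1"],
                           "ly_papp_cm_per_s": [3e-6]})
        kept, log = apply_qc(wells, ly)
        kept_keys = set(zip(kept["compound_id"], kept["cell_line"]))
        logged_keys = {(e["compound_id"], e["cell_line"]) for e in log}
        all_keys = set(zip(wells["compound_id"], wells["cell_line"]))
        assert kept_keys | logged_keys == all_keys
        assert kept_keys & logged_keys == set()


class TestRoundTrip:
    def test_noise_free_wells_reproduce_latent_er_and_full_recovery(
        self, noise_free_study
    ):
        """Generator -> transport reduction is the identity on latent ERs."""
        efflux, log = build_efflux_table(noise_free_study.wells, noise_free_study.ly)
        assert log == []
        panel = noise_free_study.panel.set_index("compound_id")
        for line in ("hMDR1", "cyMDR1", "hBCRP"):
            col = "er_hBCRP" if line == "hBCRP" else f"er_{line}"
            sub = efflux[efflux["cell_line"] == line].set_index("compound_id")
            expected = panel.loc[sub.index, col]
            np.testing.assert_allclose(sub["er_vehicle"], expected, rtol=1e-9)
        # replicate support and recovery
        assert (efflux["n_replicates"] >= 6).all()
        kept, _ = apply_qc(noise_free_study.wells, noise_free_study.ly)
        np.testing.assert_allclose(kept["recovery_pct"], 100.0, rtol=1e-9)

    def test_mock_ers_near_unity(self, study):
        efflux, _ = build_efflux_table(study.wells, study.ly)
        mock = efflux[efflux["cell_line"] == "mock"]["er_vehicle"]
        assert len(mock) > 50
        assert 0.7 < mock.median() < 1.3
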