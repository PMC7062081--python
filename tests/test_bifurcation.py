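import numpy as np
import pytest

from biofilmosc import (
    hopf_point,
    hopf_point_numeric,
    jacobian,
    scan,
    transcritical_point,
)
from biofilmosc.model import EIG_TOL, eigenvalues_from_jacobian, ntss_concentrations

from conftest import random_physical_params


class TestClosedFormThresholds:
    def test_transcritical_solves_k1GE_equals_k4(self, table1):
        assert transcritical_point(table1) == pytest.approx(2.0 / 0.3426)
        assert transcritical_point(table1) == pytest.approx(5.8377, abs=1e-4)

    def test_hopf_solves_k1GE_equals_sum_of_decays(self, table1):
        assert hopf_point(table1) == pytest.approx(8.3 / 0.3426)
        assert hopf_point(table1) == pytest.approx(24.2265, abs=1e-4)

    def test_thresholds_scale_inversely_with_k1(self, table1):
        p2 = table1.replace(k1=2 * table1.k1)
        assert transcritical_point(p2) == pytest.approx(transcritical_point(table1) / 2)
        assert hopf_point(p2) == pytest.approx(hopf_point(table1) / 2)

    def test_tss_eigenvalue_changes_sign_at_transcritical(self, table1):
        gc = transcritical_point(table1)
        for G_E, sign in [(gc - 0.1, -1), (gc + 0.1, +1)]:
            p = table1.replace(G_E=G_E)
            lead = np.max(eigenvalues_from_jacobian(jacobian((0, 0, 0), p)).real)
            assert np.sign(lead) == sign

    def test_pure_imaginary_pair_at_hopf(self, table1):
        p = table1.replace(G_E=hopf_point(table1))
        eigs = eigenvalues_from_jacobian(jacobian(ntss_concentrations(p), p))
        pair = eigs[np.abs(eigs.imag) > 1e-9]
        assert pair.size == 2
        assert np.max(np.abs(pair.real)) < 1e-6
        np.testing.assert_allclose(
            np.abs(pair.imag), np.sqrt(p.k3 * p.k5), rtol=1e-9
        )
        assert np.sqrt(p.k3 * p.k5) == pytest.approx(3.0332, abs=1e-4)


class TestNumericHopf:
    def test_matches_closed_form_for_G_E(self, table1):
        got = hopf_point_numeric(table1, "G_E", (10.0, 40.0))
        assert got == pytest.approx(hopf_point(table1), rel=1e-6)

    def test_ammonia_production_threshold(self, table1):
        # Hopf condition rearranged for k5: k5 = k1*G_E - k4 - k3
        got = hopf_point_numeric(table1, "k5", (1.0, 6.0))
        assert got == pytest.approx(table1.k - table1.k3, rel=1e-6)
        assert got == pytest.approx(4.278, abs=1e-3)

    def test_ammonia_loss_threshold(self, table1):
        got = hopf_point_numeric(table1, "k3", (1.0, 10.0))
        assert got == pytest.approx(table1.k - table1.k5, rel=1e-6)
        assert got == pytest.approx(5.978, abs=1e-3)

    def test_matches_closed_form_on_random_parameter_sets(self):
        rng = np.random.default_rng(11)
        n_checked = 0
        while n_checked < 20:
            p = random_physical_params(rng)
            gh = hopf_point(p)
            got = hopf_point_numeric(p, "G_E", (0.95 * gh, 1.5 * gh))
            assert got == pytest.approx(gh, rel=1e-6)
            # oscillation frequency at onset is sqrt(k3*k5)
            ph = p.replace(G_E=gh)
            eigs = eigenvalues_from_jacobian(jacobian(ntss_concentrations(ph), ph))
            pair = eigs[np.abs(eigs.imag) > EIG_TOL * np.abs(eigs)]
            np.testing.assert_allclose(
                np.abs(pair.imag), np.sqrt(p.k3 * p.k5), rtol=1e-6
            )
            n_checked += 1

    def test_no_sign_change_raises(self, table1):
        with pytest.raises(ValueError, match="sign change"):
            hopf_point_numeric(table1, "G_E", (26.0, 40.0))


@pytest.fixture(scope="module")
def ge_scan(table1):
    grid = np.array([3.0, 5.0, 7.0, 9.0, 12.0, 15.0, 18.0, 21.0, 26.0, 30.0])
    return scan(table1, "G_E", grid)


class TestScan:
    def test_validates_grid(self, table1):
        with pytest.raises(ValueError, match="at least 10"):
            scan(table1, "G_E", np.linspace(5, 30, 5))
        with pytest.raises(ValueError, match="sorted"):
            scan(table1, "G_E", np.linspace(30, 5, 12))
        with pytest.raises(ValueError, match="bif_param"):
            scan(table1, "b", np.linspace(1, 2, 12))

    def test_branch_crosses_zero_at_transcritical(self, table1, ge_scan):
        branch = ge_scan.table["branch_Gp"].to_numpy()
        values = ge_scan.values
        crossing = values[np.flatnonzero(np.diff(np.sign(branch)))[0]]
        gc = transcritical_point(table1)
        assert crossing < gc < crossing + 2.0

    def test_envelope_closed_below_hopf_open_beyond(self, ge_scan, table1):
        width = dict(zip(ge_scan.values, ge_scan.envelope_width()))
        table = ge_scan.table.set_index("param_value")
        for G_E in (9.0, 12.0, 15.0):
            assert width[G_E] < 1e-3
            assert table.loc[G_E, "env_min_Gp"] == pytest.approx(
                table.loc[G_E, "branch_Gp"], rel=1e-3
            )
        assert width[26.0] > 1.0
        assert width[30.0] > 10.0

    def test_classification_sequence_along_supply_axis(self, ge_scan):
        labels = ge_scan.table["classification"].tolist()
        phases = []
        for lab in labels:
            if lab not in phases:
                phases.append(lab)
        assert phases == [
            "TSS-stable-node",
            "NTSS-stable-node",
            "NTSS-stable-focus",
            "NTSS-unstable-focus",
        ]

    def test_supercritical_envelope_grows_from_zero(self, table1):
        """Just beyond the Hopf point the limit-cycle amplitude rises
        continuously from zero (supercritical), so the envelope width is
        small and increasing with distance past the threshold."""
        gh = hopf_point(table1)
        grid = np.sort(np.concatenate([np.linspace(10, 23, 8), [gh + 0.2, gh + 1.0]]))
        diagram = scan(table1, "G_E", grid)
        width = dict(zip(diagram.values, diagram.envelope_width()))
        w_near, w_far = width[gh + 0.2], width[gh + 1.0]
        assert 0 < w_near < w_far
        assert w_near < 2.5 and w_far < 7.5  # both small against the ~15 at G_E=30

    def test_csv_round_trip(self, tmp_path, ge_scan):
        path = tmp_path / "scan.csv"
        ge_scan.to_csv(path)
        header = path.read_text().splitlines()[0]
        for col in ("param_value", "branch_Gp", "env_min_Gp", "env_max_Gp", "classification"):
            assert col in header
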