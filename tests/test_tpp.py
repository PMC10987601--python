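"""2D-TPP hit calling, bootstrap FDR and activity estimation."""

import numpy as np
import pytest

from cosmotherm.core_io import (DEFAULT_CONCENTRATIONS, DEFAULT_TEMPERATURES,
                                InputNode, InputNodeSet, PKN, TppProfile,
                                make_de_frame)
from cosmotherm.tpp_analysis import (TppHit, bootstrap_fdr,
                                     estimate_tpp_activities, fit_models,
                                     stabilization_score, strict_hits)

TEMPS = np.array(DEFAULT_TEMPERATURES)
CONCS = np.array(DEFAULT_CONCENTRATIONS)


def profile(name="P", matrix=None, amplitude=0.0, noise_sd=0.0, seed=0,
            direction=1):
    rng = np.random.default_rng(seed)
    nonveh = CONCS != 0
    if matrix is None:
        s = np.zeros_like(CONCS)
        s[nonveh] = 1.0 / (1.0 + np.exp(-2.0 * (np.log10(CONCS[nonveh]))))
        A = np.zeros(len(TEMPS))
        A[len(TEMPS) // 2:] = amplitude * direction
        matrix = 1.0 + A[:, None] * s[None, :]
        noise = rng.normal(0, noise_sd, size=matrix.shape)
        noise[:, ~nonveh] = 0
        matrix = matrix + noise
    return TppProfile(protein=name, temperatures=TEMPS,
                      concentrations=CONCS, rel_abundance=matrix)


class TestFitModels:
    def test_flat_profile_f_near_zero(self):
        fit = fit_models(profile(noise_sd=0.02, seed=1))
        assert fit.F < 5.0
        assert fit.rss1 <= fit.rss0 + 1e-9

    def test_planted_stabilization_detected(self):
        # flat-profile fits at this noise level stay below F ~ 3 (see the
        # null test above); the planted dose response must stand far clear
        fit = fit_models(profile(amplitude=0.5, noise_sd=0.05, seed=2))
        assert fit.F > 5
        assert fit.direction == "stabilized"

    def test_planted_destabilization_direction(self):
        fit = fit_models(profile(amplitude=0.5, noise_sd=0.05, seed=3,
                                 direction=-1))
        assert fit.direction == "destabilized"

    def test_single_temperature_skipped(self):
        p = TppProfile("P", [50.0], CONCS, np.ones((1, 5)))
        assert fit_models(p) is None

    def test_row_offset_invariance(self):
        """Adding a constant to one temperature row leaves F unchanged."""
        base = profile(amplitude=0.4, noise_sd=0.05, seed=4)
        f0 = fit_models(base).F
        shifted = base.rel_abundance.copy()
        shifted[3, :] += 0.7
        f1 = fit_models(profile(matrix=shifted)).F
        assert f0 == pytest.approx(f1, rel=1e-6)


class TestBootstrapFdr:
    def test_identical_flat_profiles_no_hits(self):
        profs = [profile(f"P{i}", matrix=np.ones((12, 5))) for i in range(10)]
        assert bootstrap_fdr(profs, B=10, seed=0) == []

    def test_deterministic_under_seed(self):
        profs = [profile(f"P{i}", amplitude=0.5 if i < 2 else 0.0,
                         noise_sd=0.05, seed=i) for i in range(12)]
        h1 = bootstrap_fdr(profs, B=10, seed=7)
        h2 = bootstrap_fdr(profs, B=10, seed=7)
        assert [(h.protein, h.fdr) for h in h1] == \
               [(h.protein, h.fdr) for h in h2]

    def test_planted_hits_called(self):
        profs = [profile(f"HIT{i}", amplitude=0.5, noise_sd=0.05, seed=i)
                 for i in range(3)]
        profs += [profile(f"NULL{i}", noise_sd=0.05, seed=100 + i)
                  for i in range(30)]
        hits = bootstrap_fdr(profs, B=30, seed=0)
        called = {h.protein for h in hits}
        assert {"HIT0", "HIT1", "HIT2"} <= called

    def test_fdr_values_bounded_and_below_cutoff(self):
        profs = [profile(f"HIT{i}", amplitude=0.5, noise_sd=0.05, seed=i)
                 for i in range(3)]
        profs += [profile(f"NULL{i}", noise_sd=0.05, seed=200 + i)
                  for i in range(20)]
        for h in bootstrap_fdr(profs, B=20, cutoff=0.1, seed=1):
            assert 0.0 <= h.fdr < 0.1

    def test_invalid_b_errors(self):
        with pytest.raises(ValueError):
            bootstrap_fdr([profile()], B=0)


class TestAlternativeHitSets:
    def test_strict_rule_needs_both_conditions(self):
        good = profile("GOOD", amplitude=4.0, noise_sd=0.02, seed=5)
        weak_fit = profile("WEAKFIT", amplitude=0.0, noise_sd=0.3, seed=6)
        small = profile("SMALL", amplitude=0.3, noise_sd=0.02, seed=7)
        hits = strict_hits([good, weak_fit, small])
        assert [h.protein for h in hits] == ["GOOD"]

    def test_stabilization_score_monotone_in_effect(self):
        strong = profile("STRONG", amplitude=0.5, noise_sd=0.0)
        weak = profile("WEAK", amplitude=0.1, noise_sd=0.0)
        top = stabilization_score([weak, strong], k_top=1)
        assert top[0].protein == "STRONG"

    def test_zero_profile_scores_zero(self):
        top = stabilization_score([profile(matrix=np.ones((12, 5)))],
                                  k_top=1)
        assert top[0].magnitude == 0.0

    def test_planted_shifts_rank_in_top(self):
        profs = [profile(f"HIT{i}", amplitude=0.6, noise_sd=0.05, seed=i)
                 for i in range(5)]
        profs += [profile(f"NULL{i}", noise_sd=0.05, seed=300 + i)
                  for i in range(45)]
        top = {h.protein for h in stabilization_score(profs, k_top=10)}
        assert all(f"HIT{i}" in top for i in range(5))


class TestEstimateTppActivities:
    def _hit(self, prot, direction="stabilized", mag=1.0):
        return TppHit(protein=prot, direction=direction, F=20.0, fdr=0.0,
                      hit_set="fstat", magnitude=mag)

    def _kinases(self, *entries):
        return InputNodeSet.build(
            [InputNode(n, "kinase", s, 1.0) for n, s in entries])

    def test_single_consistent_kinase_gives_sign(self):
        pkn = PKN.from_edges([("K", 1, "H")])
        nodes, _ = estimate_tpp_activities([self._hit("H")], pkn,
                                           self._kinases(("K", 1)))
        assert nodes.entries[0].sign == 1
        assert nodes.entries[0].weight == 1.0

    def test_conflicting_kinases_leave_sign_unknown(self):
        pkn = PKN.from_edges([("K1", 1, "H"), ("K2", 1, "H")])
        nodes, _ = estimate_tpp_activities(
            [self._hit("H", mag=0.8)], pkn,
            self._kinases(("K1", 1), ("K2", -1)))
        e = nodes.entries[0]
        assert e.sign is None and e.weight == pytest.approx(1.0)

    def test_no_upstream_kinase_weight_only(self):
        pkn = PKN.from_edges([("X", 1, "Y")])
        nodes, _ = estimate_tpp_activities(
            [self._hit("H", mag=0.5), self._hit("G", mag=1.0)], pkn,
            self._kinases(("K", 1)))
        w = {e.node: e.weight for e in nodes}
        assert w["H"] == pytest.approx(0.5) and w["G"] == pytest.approx(1.0)

    def test_kinase_sign_filter_removes_contradicted_edge(self):
        pkn = PKN.from_edges([("K", 1, "H"), ("K", 1, "Z")])
        de = make_de_frame(["H_S1"], [-1.0], [-5.0], [1e-4], [1e-3],
                           significant=[True])
        _, filtered = estimate_tpp_activities(
            [self._hit("H")], pkn, self._kinases(("K", 1)), phospho_de=de)
        # K(+1) activating H predicts +1, but the significant site on H fell
        assert ("K", 1, "H") not in filtered.edges
        assert ("K", 1, "Z") in filtered.edges

    def test_no_phospho_keeps_pkn(self):
        pkn = PKN.from_edges([("K", 1, "H")])
        _, filtered = estimate_tpp_activities([self._hit("H")], pkn,
                                              self._kinases(("K", 1)))
        assert filtered.edges == pkn.edges
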