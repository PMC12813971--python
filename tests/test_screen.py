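"""Conformer screening: single structures, 50:50 pairs, restriction."""

import numpy as np
import pytest

from glynmr.assign import Conformer, assign, predict_table
from glynmr.forward import pcs_predict, rdc_predict
from glynmr.screen import (
    motional_restriction_summary,
    screen_pairs,
    screen_single,
)
from glynmr.sites import Observation, SiteClass
from glynmr.synthetic import make_geometry, make_tensor
from glynmr.tensor import tensor_from_c5


def site_obs_from_truth(obs, truth):
    out = {}
    for o in obs:
        g, slot = truth[o.id]
        out.setdefault(g, []).append((o, slot))
    return out


def observations_from_conformer(conformers, weights, tensor, ln, prefix="o",
                                rdc_sigma=1.6):
    """Noise-free observations from a weighted mixture of conformers."""
    obs, truth = [], {}
    for k, (slot, cls) in enumerate(
        [("first_C1", SiteClass.first_C1), ("second_C1", SiteClass.second_C1),
         ("acetyl_1", SiteClass.acetyl), ("acetyl_2", SiteClass.acetyl)]
    ):
        pcs = sum(w * pcs_predict(tensor, ln, c.labeled(slot)) for w, c in zip(weights, conformers))
        rdc = sum(w * rdc_predict(tensor, c.labeled(slot)) for w, c in zip(weights, conformers))
        oid = f"{prefix}{k}"
        obs.append(Observation(id=oid, site_class=cls, lanthanide="X",
                               pcs_ppm=pcs, rdc_hz=rdc, rdc_err=rdc_sigma))
        truth[oid] = (conformers[0].glyco_site, slot)
    return obs, truth


@pytest.fixture(scope="module")
def screen_setup(scenario):
    conformers = [c for confs in scenario.library.values() for c in confs]
    return scenario, conformers


def test_generating_conformer_ranks_first_under_both_tensors(screen_setup, noiseless_obs):
    scenario, conformers = screen_setup
    for lab in ("Tb", "Tm"):
        obs = noiseless_obs[lab]["glycan"]
        site_obs = site_obs_from_truth(obs, noiseless_obs[lab]["truth"])
        rep = screen_single(conformers, scenario.tensors[lab], scenario.lanthanide_pos, site_obs)
        for g, ss in rep.sites.items():
            gen = scenario.library[g][0].id  # mixture weight 1 on most probable
            assert ss.best_single == gen
            assert ss.best_single_chi2 == pytest.approx(0.0, abs=1e-16)
            assert ss.restriction_index == 1.0  # all accepts at 2 sigma
            # strictly smallest among distinct candidates
            others = ss.candidates[ss.candidates.conformer != gen].chi2
            assert (others > 1e-6).all()


def test_zero_tensor_and_zero_observations_tie_at_zero(screen_setup):
    scenario, conformers = screen_setup
    zero = tensor_from_c5(np.zeros(5), "Z")
    obs = [
        Observation(id=f"z{k}", site_class=cls, lanthanide="Z", pcs_ppm=0.0,
                    rdc_hz=0.0, rdc_err=1.0)
        for k, cls in enumerate([SiteClass.first_C1, SiteClass.second_C1,
                                 SiteClass.acetyl, SiteClass.acetyl])
    ]
    site_obs = {"NG1": [(obs[0], "first_C1"), (obs[1], "second_C1"),
                        (obs[2], "acetyl_1"), (obs[3], "acetyl_2")]}
    rep = screen_single(conformers, zero, scenario.lanthanide_pos, site_obs)
    assert np.allclose(rep.sites["NG1"].candidates.chi2, 0.0)


def test_accept_flag_two_sigma_boundary(screen_setup):
    scenario, conformers = screen_setup
    tensor = scenario.tensors["Tm"]
    ln = scenario.lanthanide_pos
    c = scenario.library["NG1"][0]
    base = rdc_predict(tensor, c.labeled("first_C1"))
    sigma = 1.6
    for shift, expected in [(2 * sigma, True), (2 * sigma + 1e-6, False)]:
        o = Observation(id="b", site_class=SiteClass.first_C1, lanthanide="Tm",
                        rdc_hz=base + shift, rdc_err=sigma)
        rep = screen_single([c], tensor, ln, {"NG1": [(o, "first_C1")]})
        rec = rep.sites["NG1"].per_obs[c.id][0]
        assert rec["rdc_accept"] is expected


def test_fifty_fifty_mixture_recovered_by_pair_screening(screen_setup):
    scenario, conformers = screen_setup
    tensor = scenario.tensors["Tb"]
    ln = scenario.lanthanide_pos
    pair = scenario.library["NG2"][:2]
    obs, truth = observations_from_conformer(pair, [0.5, 0.5], tensor, ln)
    site_obs = site_obs_from_truth(obs, truth)
    rep = screen_pairs(conformers, tensor, ln, site_obs)
    ss = rep.sites["NG2"]
    assert set(ss.best_pair[:2]) == {pair[0].id, pair[1].id}
    assert ss.best_pair[2] == 0.5
    assert ss.best_pair_chi2 == pytest.approx(0.0, abs=1e-16)
    assert ss.best_pair_chi2 < ss.best_single_chi2
    assert any(set(i["pair"]) == {pair[0].id, pair[1].id} for i in ss.improving_pairs)


def test_identical_pair_gives_no_improvement(screen_setup):
    scenario, _ = screen_setup
    tensor = scenario.tensors["Tm"]
    ln = scenario.lanthanide_pos
    c = scenario.library["NG1"][0]
    twin = Conformer(id="NG1-twin", glyco_site="NG1", sites=c.sites, probability=0.1)
    obs, truth = observations_from_conformer([c], [1.0], tensor, ln)
    site_obs = site_obs_from_truth(obs, truth)
    rep = screen_pairs([c, twin], tensor, ln, site_obs)
    ss = rep.sites["NG1"]
    assert ss.best_pair_chi2 == pytest.approx(ss.best_single_chi2, abs=1e-12)
    assert ss.improving_pairs == []


def test_degenerate_weights_never_beat_best_single(screen_setup):
    # with 0 and 1 in the grid the pair search contains all singles
    scenario, conformers = screen_setup
    tensor = scenario.tensors["Tm"]
    ln = scenario.lanthanide_pos
    obs, truth = observations_from_conformer(scenario.library["NG3"][:2], [0.7, 0.3], tensor, ln)
    site_obs = site_obs_from_truth(obs, truth)
    rep = screen_pairs(conformers, tensor, ln, site_obs, weight_grid=(0.0, 0.5, 1.0))
    ss = rep.sites["NG3"]
    assert ss.best_pair_chi2 <= ss.best_single_chi2 + 1e-12


def test_candidate_order_invariance(screen_setup, noiseless_obs):
    scenario, conformers = screen_setup
    tensor = scenario.tensors["Tb"]
    site_obs = site_obs_from_truth(
        noiseless_obs["Tb"]["glycan"], noiseless_obs["Tb"]["truth"]
    )
    rep1 = screen_single(conformers, tensor, scenario.lanthanide_pos, site_obs)
    rep2 = screen_single(list(reversed(conformers)), tensor, scenario.lanthanide_pos, site_obs)
    for g in rep1.sites:
        assert rep1.sites[g].best_single == rep2.sites[g].best_single
        assert list(rep1.sites[g].candidates.conformer) == list(rep2.sites[g].candidates.conformer)


def test_top_k_restriction(screen_setup, noiseless_obs):
    scenario, conformers = screen_setup
    rep = screen_single(
        conformers, scenario.tensors["Tm"], scenario.lanthanide_pos,
        site_obs_from_truth(noiseless_obs["Tm"]["glycan"], noiseless_obs["Tm"]["truth"]),
        top_k=2,
    )
    for ss in rep.sites.values():
        assert len(ss.candidates) == 2


def test_empty_site_skipped_with_warning(screen_setup):
    scenario, conformers = screen_setup
    with pytest.warns(UserWarning, match="no assigned observations"):
        rep = screen_single(conformers, scenario.tensors["Tm"], scenario.lanthanide_pos, {})
    assert rep.sites == {}


class TestMotionalRestriction:
    def test_single_conformer_site_is_restricted(self, screen_setup, noiseless_obs):
        scenario, conformers = screen_setup
        reports, by_lan = [], {}
        for lab in ("Tb", "Tm"):
            site_obs = site_obs_from_truth(
                noiseless_obs[lab]["glycan"], noiseless_obs[lab]["truth"]
            )
            rep = screen_pairs(conformers, scenario.tensors[lab],
                               scenario.lanthanide_pos, site_obs)
            reports.append(rep)
            by_lan[lab] = site_obs
        df = motional_restriction_summary(reports, by_lan).set_index("glyco_site")
        assert bool(df.loc["NG1", "restricted"])
        assert df.loc["NG1", "max_abs_rdc_hz"] > 0

    def test_isotropically_averaged_site_not_restricted(self, screen_setup):
        """A site whose data average over many isotropic conformers has
        near-zero RDCs and is matched by no single structure or pair."""
        scenario, _ = screen_setup
        tensor = scenario.tensors["Tm"]
        ln = scenario.lanthanide_pos
        _p, lib, _l = make_geometry(
            n_protein_sites=1, n_glyco_sites=1, conformers_per_site=20,
            seed=31, rmsd_floor=0.5,
        )
        many = lib["NG1"]
        obs, truth = observations_from_conformer(
            many, np.full(len(many), 1 / len(many)), tensor, ln, rdc_sigma=0.2
        )
        site_obs = site_obs_from_truth(obs, truth)
        rep = screen_pairs(many[:6], tensor, ln, site_obs, tolerance_mult=0.5)
        df = motional_restriction_summary([rep], {"Tm": site_obs}).set_index("glyco_site")
        assert not bool(df.loc["NG1", "restricted"])

    def test_empty_site_flag_undefined(self, screen_setup, noiseless_obs):
        scenario, conformers = screen_setup
        site_obs = site_obs_from_truth(
            noiseless_obs["Tm"]["glycan"], noiseless_obs["Tm"]["truth"]
        )
        with pytest.warns(UserWarning):
            rep = screen_single(
                conformers, scenario.tensors["Tm"], scenario.lanthanide_pos,
                {g: v for g, v in site_obs.items() if g != "NG2"},
            )
        df = motional_restriction_summary([rep], {"Tm": site_obs}).set_index("glyco_site")
        assert df.loc["NG2", "restricted"] is None or np.isnan(df.loc["NG2", "best_accept_fraction"])
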