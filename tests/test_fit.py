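"""Tensor determination: recovery, weighting, outlier exclusion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glynmr.forward import pcs_predict, rdc_predict
from glynmr.sites import FieldConditions, LabeledSite, Observation, SiteClass, VectorKind
from glynmr.synthetic import default_scenario, make_tensor
from glynmr.tensorfit import (
    bootstrap_tensor,
    fit_tensor,
    fit_with_exclusion,
    flag_mobile_sites,
)

from conftest import random_site

COND = FieldConditions()


def make_obs(sites, tensor, ln, rdc_subset=None, rng=None, noise=0.0, rdc_sigma=1.6):
    """Noiseless or noisy observations for explicit site lists."""
    obs = []
    for i, s in enumerate(sites):
        pcs = pcs_predict(tensor, ln, s)
        rdc = rdc_predict(tensor, s, COND) if (rdc_subset is None or i in rdc_subset) else None
        if noise and rng is not None:
            pcs = pcs + rng.normal() * max(0.15 * abs(pcs), 0.03) * noise
            rdc = None if rdc is None else rdc + rng.normal() * rdc_sigma * noise
        obs.append(
            Observation(
                id=f"o{i}",
                site_class=SiteClass.protein_methyl,
                lanthanide="X",
                pcs_ppm=pcs,
                rdc_hz=rdc,
                rdc_err=None if rdc is None else rdc_sigma,
                site_id=s.id,
            )
        )
    return obs


@pytest.fixture
def geometry():
    rng = np.random.default_rng(5)
    sites = []
    for i in range(20):
        s = random_site(rng, rmin=10, rmax=40, kind=VectorKind.methyl_axis)
        sites.append(
            LabeledSite(
                id=f"m{i}",
                site_class=SiteClass.protein_methyl,
                position=s.position,
                vector=s.vector,
                vector_kind=s.vector_kind,
            )
        )
    return sites, np.zeros(3)


def test_noiseless_recovery_and_route_consistency(geometry):
    sites, ln = geometry
    truth = make_tensor(-12.0, 0.3, seed=9)
    obs = make_obs(sites, truth, ln)
    scale = np.abs(truth.c5).max()
    joint = fit_tensor(sites, obs, ln, COND).tensor.c5
    pcs_only = fit_tensor(
        sites,
        [Observation(id=o.id, site_class=o.site_class, lanthanide="X",
                     pcs_ppm=o.pcs_ppm, site_id=o.site_id) for o in obs],
        ln,
        COND,
    ).tensor.c5
    rdc_only = fit_tensor(
        sites,
        [Observation(id=o.id, site_class=o.site_class, lanthanide="X",
                     rdc_hz=o.rdc_hz, rdc_err=o.rdc_err, site_id=o.site_id) for o in obs],
        ln,
        COND,
    ).tensor.c5
    for got in (joint, pcs_only, rdc_only):
        assert np.abs(got - truth.c5).max() / scale < 1e-8


def test_all_zero_observations_give_zero_tensor(geometry):
    sites, ln = geometry
    obs = [
        Observation(id=f"o{i}", site_class=SiteClass.protein_methyl, lanthanide="X",
                    pcs_ppm=0.0, site_id=s.id)
        for i, s in enumerate(sites)
    ]
    fit = fit_tensor(sites, obs, ln, COND)
    assert np.allclose(fit.tensor.c5, 0.0)
    assert all(r == 0.0 for r in fit.residuals.values())


def test_too_few_and_collinear_geometries_rejected(geometry):
    sites, ln = geometry
    truth = make_tensor(-12.0, 0.3, seed=9)
    with pytest.raises(ValueError, match="at least"):
        fit_tensor(sites[:2], make_obs(sites[:2], truth, ln, rdc_subset=set()), ln, COND)
    # all sites along one axis with identical vectors: rank-deficient
    bad = [
        LabeledSite(id=f"b{i}", site_class=SiteClass.protein_methyl,
                    position=np.array([0.0, 0.0, 10.0 + i]),
                    vector=np.array([0.0, 0.0, 1.0]),
                    vector_kind=VectorKind.methyl_axis)
        for i in range(8)
    ]
    with pytest.raises(ValueError, match="null direction"):
        fit_tensor(bad, make_obs(bad, truth, ln), ln, COND)


def test_fit_equivariance_under_rotation(geometry):
    sites, ln = geometry
    truth = make_tensor(-12.0, 0.3, seed=11)
    obs = make_obs(sites, truth, ln)
    q = Rotation.random(rng=np.random.default_rng(4)).as_matrix()
    rot_sites = [
        LabeledSite(id=s.id, site_class=s.site_class, position=q @ s.position,
                    vector=q @ s.vector, vector_kind=s.vector_kind)
        for s in sites
    ]
    f1 = fit_tensor(sites, obs, ln, COND)
    f2 = fit_tensor(rot_sites, obs, q @ ln, COND)
    assert np.allclose(f2.tensor.principal_values, f1.tensor.principal_values, atol=1e-9)
    assert np.allclose(f2.tensor.matrix, q @ f1.tensor.matrix @ q.T, atol=1e-8)


def test_removing_observation_never_raises_weighted_residual_norm(geometry):
    sites, ln = geometry
    truth = make_tensor(-12.0, 0.3, seed=13)
    rng = np.random.default_rng(21)
    obs = make_obs(sites, truth, ln, rng=rng, noise=1.0)

    def weighted_norm(fit, keep_ids):
        return sum(
            (fit.residuals[r] / fit.sigmas[r]) ** 2
            for r in fit.residuals
            if r.split(":")[0] in keep_ids
        )

    full = fit_tensor(sites, obs, ln, COND)
    for drop in (0, 7, 15):
        keep = [o for i, o in enumerate(obs) if i != drop]
        keep_ids = {o.id for o in keep}
        refit = fit_tensor(sites, keep, ln, COND)
        assert weighted_norm(refit, keep_ids) <= weighted_norm(full, keep_ids) + 1e-9


class TestExclusion:
    def corrupt(self, obs, idx, k=10.0):
        o = obs[idx]
        return obs[:idx] + [
            Observation(id=o.id, site_class=o.site_class, lanthanide=o.lanthanide,
                        pcs_ppm=o.pcs_ppm + k * o.pcs_err, pcs_err=o.pcs_err,
                        rdc_hz=o.rdc_hz, rdc_err=o.rdc_err, site_id=o.site_id)
        ] + obs[idx + 1:]

    def test_clean_data_no_exclusions(self, geometry):
        sites, ln = geometry
        truth = make_tensor(-12.0, 0.3, seed=15)
        rng = np.random.default_rng(3)
        obs = make_obs(sites, truth, ln, rng=rng, noise=0.3)
        fit = fit_with_exclusion(sites, obs, ln, COND)
        assert fit.excluded == []

    def test_single_corrupted_observation_excluded(self, geometry):
        sites, ln = geometry
        truth = make_tensor(-12.0, 0.3, seed=15)
        rng = np.random.default_rng(8)
        obs = self.corrupt(make_obs(sites, truth, ln, rng=rng, noise=1.0), 4)
        fit = fit_with_exclusion(sites, obs, ln, COND)
        assert fit.excluded_ids == ["o4:pcs"]
        rel = abs(fit.tensor.dchi_ax - truth.dchi_ax) / abs(truth.dchi_ax)
        assert rel < 0.15

    def test_two_outliers_excluded_in_decreasing_residual_order(self, geometry):
        sites, ln = geometry
        truth = make_tensor(-12.0, 0.3, seed=15)
        obs = make_obs(sites, truth, ln)  # noiseless background
        obs = self.corrupt(self.corrupt(obs, 2, k=8.0), 9, k=14.0)
        fit = fit_with_exclusion(sites, obs, ln, COND)
        assert fit.excluded_ids[:2] == ["o9:pcs", "o2:pcs"]

    def test_blacklist_removed_up_front(self, geometry):
        sites, ln = geometry
        truth = make_tensor(-12.0, 0.3, seed=15)
        obs = make_obs(sites, truth, ln)
        fit = fit_with_exclusion(sites, obs, ln, COND, motional_blacklist=["m3", "m7"])
        reasons = dict(fit.excluded)
        assert reasons["o3:pcs"] == "motional_blacklist"
        assert reasons["o7:rdc"] == "motional_blacklist"
        # residuals still reported for excluded rows
        assert "o3:pcs" in fit.residuals

    def test_k_sigma_must_be_positive(self, geometry):
        sites, ln = geometry
        truth = make_tensor(-12.0, 0.3, seed=15)
        obs = make_obs(sites, truth, ln)
        with pytest.raises(ValueError):
            fit_with_exclusion(sites, obs, ln, COND, k_sigma=0.0)


def test_recovery_statistics_and_bootstrap_coverage():
    """Paper-scale conditions (20 PCS + 11 RDC, 15%/0.03 ppm + 1.6 Hz
    noise): median relative dchi_ax error < 10%, bootstrap 95% interval
    covers truth in >= 85% of replicates."""
    scen = default_scenario(seed=0)
    truth = scen.tensors["Tm"].dchi_ax
    errs, covered = [], 0
    n_rep = 100
    for rep in range(n_rep):
        obs = scen.observables(noise_scale=1.0, seed=50_000 + rep)["Tm"]["protein"]
        fit = fit_tensor(scen.protein_sites, obs, scen.lanthanide_pos, COND)
        errs.append(abs(fit.tensor.dchi_ax - truth) / abs(truth))
        boot = bootstrap_tensor(
            scen.protein_sites, obs, scen.lanthanide_pos, COND, n_boot=100, seed=rep
        )
        lo, hi = np.percentile(boot, [2.5, 97.5])
        covered += int(lo <= truth <= hi)
    assert np.median(errs) < 0.10
    assert covered / n_rep >= 0.85


def test_flag_mobile_sites():
    rng = np.random.default_rng(2)
    n_frames = 400
    rigid = np.tile(np.array([0.0, 0.0, 1.0]), (n_frames, 1))
    wobble = rigid + rng.normal(scale=0.15, size=(n_frames, 3))
    isotropic = rng.normal(size=(n_frames, 3))
    vecs = np.stack([rigid, wobble, isotropic], axis=1)
    flagged = flag_mobile_sites(["rigid", "wobble", "iso"], vecs, s2_threshold=0.8)
    assert "rigid" not in flagged
    assert "iso" in flagged
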