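"""Shared fixtures: small phantoms and cached reconstructions.

Desk-scale problem sizes (16^3 and smaller volumes, 36 projections,
8 azimuthal bins) keep the whole suite fast while exercising every
stage of the pipeline; expensive reconstructions are session-scoped so
multiple tests can interrogate the same fit.
"""

import warnings

import numpy as np
import pytest

import sigtt


@pytest.fixture(scope="session")
def rank2_recovery():
    """Noiseless 16^3 rank-2 phantom, 36 projections, ell_max=2 fit."""
    spec = sigtt.PhantomSpec(
        (16, 16, 16), symmetry_class="rank2", n_sources=2, seed=3
    )
    truth = sigtt.synthesize_field(spec)
    geometry = sigtt.default_acquisition((16, 16, 16))
    data = sigtt.simulate_measurements(truth, geometry)
    model = sigtt.SAXSTensorTomography(data, geometry, ell_max=2, lam=1e-3)
    results = model.fit(max_iter=300, tolerance=1e-10)
    return {
        "spec": spec,
        "truth": truth,
        "geometry": geometry,
        "data": data,
        "model": model,
        "results": results,
        "mask": spec.support_mask,
    }


@pytest.fixture(scope="session")
def zonal_snr_study():
    """16^3 zonal phantom (ell_max=12 truth), ell_max=6 fits at 4 SNRs."""
    spec = sigtt.PhantomSpec(
        (16, 16, 16), symmetry_class="zonal", n_sources=4, seed=7
    )
    truth = sigtt.synthesize_field(spec)
    geometry = sigtt.default_acquisition((16, 16, 16))
    medians = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for snr in (40.0, 15.0, 8.0, 4.0):
            data = sigtt.simulate_measurements(truth, geometry, snr=snr, seed=11)
            res = sigtt.SAXSTensorTomography(data, geometry, ell_max=6).fit(
                max_iter=150
            )
            r2 = res.r_squared_map(truth)
            medians[snr] = float(np.nanmedian(r2[spec.support_mask]))
    return {"spec": spec, "truth": truth, "medians": medians}


@pytest.fixture(scope="session")
def high_order_comparison():
    """Full vs rank-2-restricted fits of a 16^3 high-order phantom."""
    spec = sigtt.PhantomSpec(
        (16, 16, 16), symmetry_class="high_order", n_sources=5, seed=9
    )
    truth = sigtt.synthesize_field(spec)
    geometry = sigtt.default_acquisition((16, 16, 16))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = sigtt.simulate_measurements(truth, geometry, snr=30.0, seed=13)
        full = sigtt.SAXSTensorTomography(data, geometry, ell_max=6).fit(
            max_iter=150
        )
        rank2 = sigtt.SAXSTensorTomography(data, geometry, mode="rank2").fit(
            max_iter=150
        )
    mask = spec.support_mask
    return {
        "full_median": float(np.nanmedian(full.r_squared_map(truth)[mask])),
        "rank2_median": float(np.nanmedian(rank2.r_squared_map(truth)[mask])),
    }


@pytest.fixture(scope="session")
def mode_equivalence():
    """rank2 mode vs full mode at ell_max=2 on identical data."""
    spec = sigtt.PhantomSpec(
        (12, 12, 12), symmetry_class="rank2", n_sources=2, seed=3
    )
    truth = sigtt.synthesize_field(spec)
    geometry = sigtt.default_acquisition((12, 12, 12))
    data = sigtt.simulate_measurements(truth, geometry)
    kwargs = dict(max_iter=400, tolerance=1e-12)
    full = sigtt.SAXSTensorTomography(data, geometry, ell_max=2, lam=1e-3).fit(
        seed=1, **kwargs
    )
    rank2 = sigtt.SAXSTensorTomography(
        data, geometry, mode="rank2", lam=1e-3
    ).fit(seed=2, **kwargs)
    return {"full_loss": full.record.final_loss, "rank2_loss": rank2.record.final_loss}


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
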