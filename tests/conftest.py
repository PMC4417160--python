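import numpy as np
import pytest

from oligou import synthetic as syn

STANDARD_CONCS = [0, 2, 5, 10, 20, 40, 60, 90, 130, 200, 300, 400]


@pytest.fixture
def standard_concs():
    return list(STANDARD_CONCS)


@pytest.fixture
def noiseless_titration():
    return syn.gen_titration(
        kd_uM=50.0, r_free=0.05, r_bound=0.20, rna_total_uM=7.1,
        protein_concs=STANDARD_CONCS, noise_sd=0.0, seed=0,
    )


@pytest.fixture
def small_ensemble():
    return syn.gen_ensemble(n_models=4, n_residues=10, jitter_A=0.3, seed=11)


def grid_search_kd(series, kd_grid, rf_grid, rb_grid):
    """Independent exhaustive-grid SSE minimizer over (Kd, r_free, r_bound).

    Vectorized brute force over the full grid; used as the oracle against the
    non-linear least-squares fit.
    """
    from oligou.isotherm import fraction_bound

    p = series.protein_uM
    r = series.anisotropy
    fb = np.array([fraction_bound(p, series.rna_total_uM, kd) for kd in kd_grid])
    # shape: (kd, rf, rb, points)
    rf = np.asarray(rf_grid)[None, :, None, None]
    rb = np.asarray(rb_grid)[None, None, :, None]
    pred = rf + (rb - rf) * fb[:, None, None, :]
    sse = ((pred - r) ** 2).sum(axis=-1)
    i, j, k = np.unravel_index(np.argmin(sse), sse.shape)
    return kd_grid[i], rf_grid[j], rb_grid[k], float(sse[i, j, k])
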