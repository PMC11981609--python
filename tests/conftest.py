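import numpy as np
import pytest

from bcdms import counts as counts_mod
from bcdms import glmm, simulate


@pytest.fixture(scope="session")
def small_sim():
    """One subregion, 2 positions x 4 variants, 2 conditions x 2 replicates."""
    cfg = simulate.SimConfig(
        n_positions=2,
        n_variants_per_position=4,
        barcodes_per_variant=8,
        conditions=("DMSO", "aMSH"),
        replicates_per_condition=2,
        sigma=0.3,
        theta=5.0,
        baseline_mean=100.0,
        seed=1,
    )
    design = simulate.make_design(cfg)
    counts, sheet, truth = simulate.simulate_counts(cfg, design)
    sheet = counts_mod.compute_offsets(counts, sheet)
    return cfg, design, counts, sheet, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    _, _, counts, sheet, _ = small_sim
    data = glmm.build_position_dataset(counts, sheet, 1)
    return data, glmm.fit_position_model(data)


def make_constructed_fit(
    beta_cond,
    beta_var,
    cov=None,
    conditions=("DMSO", "Ipsen17"),
    sigma2=0.1,
    theta=5.0,
    mean_offset=0.0,
):
    """Hand-built PositionFit for analytic contrast/marginal-mean tests."""
    beta_cond = np.asarray(beta_cond, float)
    beta_var = np.atleast_2d(np.asarray(beta_var, float))
    V, C = beta_var.shape
    n_fixed = C + V * C
    if cov is None:
        cov = np.zeros((n_fixed, n_fixed))
    variants = [f"V{i + 1}" for i in range(V)]
    return glmm.PositionFit(
        position=1,
        conditions=list(conditions),
        variants=variants,
        variant_alt={v: "A" for v in variants},
        variant_position={v: 1 for v in variants},
        beta_cond=beta_cond,
        beta_var=beta_var,
        sigma2=sigma2,
        theta=theta,
        cov_fixed=np.asarray(cov, float),
        loglik=0.0,
        converged=True,
        mean_offset=mean_offset,
    )
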