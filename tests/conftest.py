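"""Shared helpers: small synthetic instances used across the test modules."""

import numpy as np

from bvsmis import (
    SelfReportPanel,
    SimulationDesign,
    TestAccuracy,
    build_partition,
    generate_dataset,
    observation_matrix,
)

DIABETES_SELF_REPORT = TestAccuracy(0.61, 0.995)  # validated diabetes self-report operating point


def simulated_instance(rng, n=50):
    """An instance from the generative regime the package targets: scheduled visits,
    moderate effect sizes, one of the study's accuracy settings, optional NTFP."""
    accs = [(1.0, 1.0), (1.0, 0.9), (0.75, 1.0), (0.61, 0.995)]
    acc = TestAccuracy(*accs[rng.integers(4)])
    design = SimulationDesign(
        n=n,
        P=4,
        n_true=2,
        beta_true=float(rng.uniform(0.0, 1.2)),
        cir=float(rng.uniform(0.1, 0.4)),
        accuracy=acc,
        design="NTFP" if (acc.perfect or rng.random() < 0.5) else "NMISS",
    )
    ds = generate_dataset(design, rng)
    part = build_partition(ds.panels)
    obs = observation_matrix(ds.panels, part, acc)
    beta = rng.normal(0, 0.5, size=4)
    return ds, part, obs, ds.Z.values, beta


def random_instance(rng, n=20, J=4, imperfect=True):
    """A random observation-matrix instance with covariates, for oracle checks."""
    times = np.sort(rng.uniform(0.5, 8.0, size=J))
    panels = []
    for i in range(n):
        nv = rng.integers(1, J + 1)
        idx = np.sort(rng.choice(J, size=nv, replace=False))
        results = rng.integers(0, 2, size=nv)
        panels.append(SelfReportPanel(f"s{i}", times[idx], results))
    acc = TestAccuracy(rng.uniform(0.5, 1.0), rng.uniform(0.8, 1.0)) if imperfect else TestAccuracy(1, 1)
    part = build_partition(panels)
    obs = observation_matrix(panels, part, acc)
    P = int(rng.integers(1, 4))
    Z = rng.normal(size=(n, P))
    beta = rng.normal(0, 0.7, size=P)
    theta = rng.dirichlet(np.ones(part.J + 1))
    return panels, part, acc, obs, Z, beta, theta
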