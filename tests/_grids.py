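"""Shared toy-grid constructors for posterior/policy tests."""

import numpy as np

from aromat.posterior import PosteriorGrid, PriorConfig


def toy_grid(tau_vals, lam_vals, slope=0.5):
    """Uniform-mass grid on explicit axes (bypasses PriorConfig geometry)."""
    tau = np.asarray(tau_vals, dtype=float)
    lam = np.asarray(lam_vals, dtype=float)
    mass = np.full((len(tau), len(lam)), 1.0 / (len(tau) * len(lam)))
    cfg = PriorConfig(slope=slope)
    return PosteriorGrid(tau_axis=tau, lambda_axis=lam, mass=mass, config=cfg)


def degenerate_grid(log_tau, lam, slope=0.5):
    return toy_grid([log_tau], [lam], slope)
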