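"""Shared builders for the test suite."""

import numpy as np
import pandas as pd

from feederdiff import DiffusionDesign, PeriodWindow
from feederdiff.synthetic import simulate_diffusion

ORIGIN = pd.Timestamp("2021-01-04")


def vframe(rows, origin=ORIGIN):
    """Visit table from (seconds_offset, individual_id[, feeder_id]) tuples."""
    recs = []
    for row in rows:
        sec, ind = row[0], row[1]
        feeder = row[2] if len(row) > 2 else "F1"
        recs.append((origin + pd.Timedelta(seconds=sec), ind, feeder))
    return pd.DataFrame(recs, columns=["timestamp", "individual_id", "feeder_id"])


def window(role, feeder="F1", index=1, start=ORIGIN, days=7):
    return PeriodWindow(
        period_index=index,
        feeder_id=feeder,
        role=role,
        start=start,
        end=start + pd.Timedelta(days=days),
    )


def brute_force_modsri_numerator(a, b, tau):
    """Oracle: all-pairs scan counting visits with a partner within tau."""
    n = 0
    for t in a:
        if any(abs(t - u) <= tau for u in b):
            n += 1
    for u in b:
        if any(abs(t - u) <= tau for t in a):
            n += 1
    return n


def random_network(rng, n, density=0.3):
    """Sparse symmetric weighted network with zero diagonal."""
    A = np.triu((rng.random((n, n)) < density) * rng.random((n, n)), 1)
    return A + A.T


def random_designs(rng, n_diff, n_ind, s, beta=0.0, ilv_scale=0.5):
    """Diffusions simulated from the additive OADA model on random networks."""
    designs = []
    for _ in range(n_diff):
        A = random_network(rng, n_ind)
        x = ilv_scale * rng.standard_normal(n_ind)
        order = simulate_diffusion(A, s, beta, x, rng)
        designs.append(DiffusionDesign(A, order, x))
    return designs
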