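"""Independent reference implementations used to check the library.

These deliberately use plain loops / explicit enumeration / generic sparse
solvers rather than the library's own code paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.sparse import csr_matrix, diags, eye, kron
from scipy.sparse.linalg import spsolve


def entropy_plain(p) -> float:
    """Plain-Python Shannon entropy with 0 ln 0 = 0."""
    total = 0.0
    for v in np.asarray(p, dtype=float).ravel():
        if v > 0:
            total -= v * math.log(v)
    return total


def expected_entropy_change_bruteforce(p, cell_xy, candidate, radius, p_hit):
    """Three-outcome enumeration of the expected entropy change.

    Explicitly constructs the found / hit / no-hit posteriors, computes each
    entropy and combines with the outcome probabilities.  ``p`` is the prior
    over cells at coordinates ``cell_xy`` (n, 2); ``p_hit`` the per-cell hit
    probability for a source in that cell.
    """
    p = np.asarray(p, dtype=float)
    cell_xy = np.asarray(cell_xy, dtype=float)
    p_hit = np.asarray(p_hit, dtype=float)
    s_now = entropy_plain(p)

    inside = [i for i in range(p.size)
              if math.hypot(cell_xy[i, 0] - candidate[0],
                            cell_xy[i, 1] - candidate[1]) < radius]
    p_star = sum(p[i] for i in inside)
    # outcome 1: source found at the candidate -> entropy collapses to 0
    ds_found = -s_now
    if p_star >= 1.0 - 1e-12:
        return p_star * ds_found, p_star
    # condition on not-found
    q = p.copy()
    for i in inside:
        q[i] = 0.0
    q = q / q.sum()
    prob_hit = float(sum(q[i] * p_hit[i] for i in range(p.size)))
    post_hit = np.array([q[i] * p_hit[i] for i in range(p.size)])
    post_hit = post_hit / post_hit.sum() if post_hit.sum() > 0 else post_hit
    post_nohit = np.array([q[i] * (1.0 - p_hit[i]) for i in range(p.size)])
    post_nohit = post_nohit / post_nohit.sum() if post_nohit.sum() > 0 else post_nohit
    ds_not_found = (prob_hit * (entropy_plain(post_hit) - s_now)
                    + (1.0 - prob_hit) * (entropy_plain(post_nohit) - s_now))
    return p_star * ds_found + (1.0 - p_star) * ds_not_found, p_star


def solve_advection_diffusion_decay(params, h=2.5, x_range=(-120.0, 280.0),
                                    y_range=(-160.0, 160.0)):
    """Steady-state concentration of D lap(c) - V dc/dx - c/tau + R delta = 0
    on a Dirichlet-zero rectangle, by sparse direct solve; returns the
    implied encounter rate field and the interior grids."""
    d, v = params.diffusivity, params.wind_speed
    tau, r = params.particle_lifetime, params.emission_rate
    xs = np.arange(x_range[0], x_range[1] + h, h)
    ys = np.arange(y_range[0], y_range[1] + h, h)
    nx, ny = len(xs), len(ys)
    ex, ey = np.ones(nx - 2), np.ones(ny - 2)
    lx = diags([ex[:-1] * (d / h ** 2 + v / (2 * h)), -ex * 2 * d / h ** 2,
                ex[:-1] * (d / h ** 2 - v / (2 * h))], [-1, 0, 1])
    ly = diags([ey[:-1] * d / h ** 2, -ey * 2 * d / h ** 2,
                ey[:-1] * d / h ** 2], [-1, 0, 1])
    a_mat = (kron(eye(ny - 2), lx) + kron(ly, eye(nx - 2))
             - (1.0 / tau) * eye((nx - 2) * (ny - 2)))
    b = np.zeros((ny - 2) * (nx - 2))
    si = int(np.argmin(np.abs(xs[1:-1])))
    sj = int(np.argmin(np.abs(ys[1:-1])))
    b[sj * (nx - 2) + si] = -r / h ** 2
    c = spsolve(csr_matrix(a_mat), b).reshape(ny - 2, nx - 2)
    rate = (2.0 * math.pi * d / math.log(params.correlation_length
                                         / params.agent_radius)) * c
    xg, yg = np.meshgrid(xs[1:-1], ys[1:-1])
    return rate, xg, yg, (xs[0], xs[-1], ys[0], ys[-1])


def binned_means_bruteforce(values, covariate, edges):
    """Group-by-bin means via an explicit per-element loop."""
    sums = [0.0] * (len(edges) - 1)
    counts = [0] * (len(edges) - 1)
    for v, c in zip(values, covariate):
        for b in range(len(edges) - 1):
            lo, hi = edges[b], edges[b + 1]
            last = b == len(edges) - 2
            if (lo <= c < hi) or (last and c == hi):
                sums[b] += v
                counts[b] += 1
                break
    return [(sums[b] / counts[b] if counts[b] else float("nan"), counts[b])
            for b in range(len(edges) - 1)]


def rmse_direct(ds, eds, n):
    """One-line evaluation of the windowed error formula."""
    pairs = [(ds[i + 1], eds[i]) for i in range(len(ds) - 1)]
    out = []
    for b in range(len(pairs) // n):
        block = pairs[b * n:(b + 1) * n]
        out.append(math.sqrt(sum((x - y) ** 2 for x, y in block) / n))
    return out


def random_belief(rng, grid):
    """Random normalized belief on an existing lattice (some zero cells)."""
    p = rng.gamma(0.5, size=grid.n_cells)
    zero = rng.random(grid.n_cells) < 0.2
    p[zero] = 0.0
    if p.sum() == 0:
        p[0] = 1.0
    return p / p.sum()
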