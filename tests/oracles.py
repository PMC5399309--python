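"""Independent reference implementations used only to check the package.

These deliberately re-derive results by the most literal route available —
an exhaustive window scan for run detection and a derivative-free
grid-refinement likelihood maximiser for the logistic model — so they share
no code path with the implementations they validate.
"""

from __future__ import annotations

import itertools

import numpy as np

from mmcsb import Breath, DetectorConfig


def brute_force_lpm_windows(breaths: list[Breath], config: DetectorConfig):
    """All breath windows that satisfy the run definition, literally.

    A window [i, j] qualifies iff every breath is large, it has at least
    ``min_breaths_per_run`` breaths, no internal quiescent gap longer than
    the maximum breath duration, it cannot be extended on either side
    (maximality), and its amplitude sequence rises to a single zenith then
    falls, each step within the envelope tolerance.
    """
    tol = config.envelope_tolerance_mm + 1e-9
    max_gap = config.breath_duration_bounds_s[1] + 1e-9

    def connected(i, j):
        return all(
            breaths[k + 1].t_start - breaths[k].t_end <= max_gap for k in range(i, j)
        )

    def unimodal(amps):
        for z in range(len(amps)):
            ok_up = all(amps[k + 1] >= amps[k] - tol for k in range(z))
            ok_down = all(amps[k + 1] <= amps[k] + tol for k in range(z, len(amps) - 1))
            if ok_up and ok_down:
                return True
        return False

    n = len(breaths)
    windows = []
    for i, j in itertools.combinations_with_replacement(range(n), 2):
        if j - i + 1 < config.min_breaths_per_run:
            continue
        if not all(b.is_large for b in breaths[i : j + 1]):
            continue
        if not connected(i, j):
            continue
        left_ext = (
            i > 0
            and breaths[i - 1].is_large
            and breaths[i].t_start - breaths[i - 1].t_end <= max_gap
        )
        right_ext = (
            j < n - 1
            and breaths[j + 1].is_large
            and breaths[j + 1].t_start - breaths[j].t_end <= max_gap
        )
        if left_ext or right_ext:
            continue
        if not unimodal([b.amplitude_mm for b in breaths[i : j + 1]]):
            continue
        windows.append((i, j))
    return windows


def grid_search_logistic_mle(design: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Maximise the Bernoulli log-likelihood by iterative grid refinement.

    ``design`` holds rows [1, lpm, spm]; ``counts`` rows [n_pos, n_neg].
    A 3^3 stencil pattern search with step halving converges on the strictly
    concave log-likelihood to ~1e-5 without derivatives or IRLS.
    """

    def loglik(beta):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(counts[:, 0] * np.log(p) + counts[:, 1] * np.log(1 - p)))

    beta = np.zeros(3)
    best = loglik(beta)
    step = 2.0
    moves = [np.array(d) for d in itertools.product((-1, 0, 1), repeat=3)]
    while step > 1e-6:
        improved = False
        for d in moves:
            cand = beta + step * d
            ll = loglik(cand)
            if ll > best + 1e-13:
                beta, best, improved = cand, ll, True
        if not improved:
            step /= 2.0
    return beta
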