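"""Independent brute-force reference implementations.

Deliberately naive (per-cell double loops, explicit rank counting) so they
stay independent of the vectorized code paths they check.
"""

import numpy as np


def naive_bandwidths(spec, counts, threshold):
    """Per-cell adaptive radius by explicit distance-sorted accumulation."""
    radii = np.zeros(spec.shape)
    centers = [
        [spec.cell_center(r, c) for c in range(spec.n_cols)] for r in range(spec.n_rows)
    ]
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            x0, y0 = centers[r][c]
            dists = []
            for rr in range(spec.n_rows):
                for cc in range(spec.n_cols):
                    x1, y1 = centers[rr][cc]
                    d = ((x1 - x0) ** 2 + (y1 - y0) ** 2) ** 0.5
                    dists.append((d, counts[rr, cc]))
            dists.sort(key=lambda t: t[0])
            cum = 0.0
            for d, p in dists:
                cum += p
                if cum >= threshold:
                    radii[r, c] = d
                    break
    return radii


def naive_kernel_sums(spec, values, radii):
    """Sum of `values` over cells whose centers lie within each cell's radius."""
    out = np.zeros(spec.shape)
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            x0, y0 = spec.cell_center(r, c)
            total = 0.0
            for rr in range(spec.n_rows):
                for cc in range(spec.n_cols):
                    x1, y1 = spec.cell_center(rr, cc)
                    d = ((x1 - x0) ** 2 + (y1 - y0) ** 2) ** 0.5
                    if d <= radii[r, c]:
                        total += values[rr, cc]
            out[r, c] = total
    return out


def naive_mc_pvalue(observed, null_stack):
    """Rank-counting Monte-Carlo p: (1 + #{null >= obs}) / (n + 1)."""
    n_sims = len(null_stack)
    out = np.zeros(observed.shape)
    for idx in np.ndindex(observed.shape):
        n_ge = sum(1 for sim in null_stack if sim[idx] >= observed[idx])
        out[idx] = (1 + n_ge) / (n_sims + 1)
    return out
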