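"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's analytic code paths: the aperture
oracle rasterizes the open region at 0.1 mm and counts pixels and boundary
edges; the gEUD oracle evaluates the power-mean sum with 50-digit
arbitrary-precision arithmetic.
"""

import numpy as np


def rasterize_aperture(x1, x2, boundaries, jaw_x, jaw_y, px=0.1, pad=5.0):
    """Pixel-count area and boundary-edge-count perimeter of an MLC aperture."""
    lo = min(boundaries[0], min(jaw_y[0], min(x1))) - pad
    hi = max(boundaries[-1], max(jaw_y[1], max(x2))) + pad
    xs = np.arange(lo, hi, px) + px / 2.0
    ys = xs.copy()
    img = np.zeros((ys.size, xs.size), dtype=bool)
    for k in range(len(x1)):
        y0, y1 = max(boundaries[k], jaw_y[0]), min(boundaries[k + 1], jaw_y[1])
        if y1 <= y0:
            continue
        a, b = max(x1[k], jaw_x[0]), min(x2[k], jaw_x[1])
        if b <= a:
            continue
        rows = (ys >= y0) & (ys < y1)
        cols = (xs >= a) & (xs < b)
        img[np.ix_(rows, cols)] = True
    area = img.sum() * px * px
    ii = img.astype(np.int8)
    edges = np.abs(np.diff(ii, axis=0)).sum() + np.abs(np.diff(ii, axis=1)).sum()
    edges += ii[0, :].sum() + ii[-1, :].sum() + ii[:, 0].sum() + ii[:, -1].sum()
    return area, edges * px


def geud_mp(diff_volume, centers, a, floor=0.01, dps=50):
    """Arbitrary-precision evaluation of the generalized power mean."""
    import mpmath
    with mpmath.workdps(dps):
        total = mpmath.mpf(0)
        for v, d in zip(diff_volume, centers):
            if v <= 0:
                continue
            dd = mpmath.mpf(max(float(d), floor))
            total += mpmath.mpf(float(v)) * dd ** mpmath.mpf(a)
        return float(total ** (1 / mpmath.mpf(a)))
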