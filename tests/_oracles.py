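"""Independent reference implementations used only to check the package.

Deliberately naive: plain-Python summation loops and exact rational
arithmetic, sharing no code with the implementation under test.
"""

from fractions import Fraction


def brute_q_tau(thetas, ses):
    """Cochran's Q and DL tau-squared by direct summation."""
    k = len(thetas)
    w = [1.0 / s / s for s in ses]
    sw = 0.0
    swt = 0.0
    for wi, ti in zip(w, thetas):
        sw += wi
        swt += wi * ti
    pooled = swt / sw
    q = 0.0
    for wi, ti in zip(w, thetas):
        q += wi * (ti - pooled) ** 2
    sw2 = 0.0
    for wi in w:
        sw2 += wi * wi
    c = sw - sw2 / sw
    tau2 = max(0.0, (q - (k - 1)) / c)
    return q, tau2


def fprp_exact(alpha, power, prior):
    """FPRP as an exact rational number."""
    a = Fraction(alpha)
    pw = Fraction(power)
    pi = Fraction(prior)
    num = a * (1 - pi)
    return num / (num + pw * pi)


def ols_intercept(x, y):
    """Closed-form simple-regression intercept and its standard error."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    rss = sum((yi - intercept - slope * xi) ** 2 for xi, yi in zip(x, y))
    sigma2 = rss / (n - 2)
    se_int = (sigma2 * (1.0 / n + mx * mx / sxx)) ** 0.5
    return intercept, se_int
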