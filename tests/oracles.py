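"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops / exhaustive enumeration,
deliberately sharing no code with the package, so that agreement between
the two routes is meaningful.
"""

import math

import numpy as np


def glcm_bruteforce(q, levels, offset=(0, 1), symmetric=True):
    """Co-occurrence probabilities of a pre-quantized ROI by explicit pair
    enumeration."""
    dr, dc = offset
    P = np.zeros((levels, levels))
    H, W = q.shape
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                P[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    P[q[r2, c2], q[r, c]] += 1
    return P / P.sum()


def haralick_bruteforce(P):
    """(energy, contrast, correlation, entropy, homogeneity) by double loop."""
    L = P.shape[0]
    energy = contrast = entropy = homogeneity = 0.0
    mu_i = mu_j = 0.0
    for i in range(L):
        for j in range(L):
            mu_i += i * P[i, j]
            mu_j += j * P[i, j]
    var_i = var_j = cov = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            energy += p * p
            contrast += p * (i - j) ** 2
            var_i += p * (i - mu_i) ** 2
            var_j += p * (j - mu_j) ** 2
            cov += p * (i - mu_i) * (j - mu_j)
            if p > 0:
                entropy -= p * math.log2(p)
            homogeneity += p / (1.0 + abs(i - j))
    corr = cov / math.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else 0.0
    return energy, contrast, corr, entropy, homogeneity


def moments_bruteforce(values):
    """(mean, variance, std, skewness, kurtosis) by explicit summation."""
    vals = list(np.asarray(values, dtype=float).ravel())
    n = len(vals)
    mean = sum(vals) / n
    m2 = sum((v - mean) ** 2 for v in vals) / n
    m3 = sum((v - mean) ** 3 for v in vals) / n
    m4 = sum((v - mean) ** 4 for v in vals) / n
    if m2 == 0:
        return mean, 0.0, 0.0, 0.0, 0.0
    return mean, m2, math.sqrt(m2), m3 / m2 ** 1.5, m4 / m2 ** 2 - 3.0


def metrics_bruteforce(X, Y, peak=255.0, c1=(0.01 * 255) ** 2,
                       c2=(0.03 * 255) ** 2):
    """All nine quality metrics by explicit double loops."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    m, n = X.shape
    se = sx = sy = sxx = syy = sxy = sabs = 0.0
    maxd = 0.0
    for k in range(m):
        for l in range(n):
            d = X[k, l] - Y[k, l]
            se += d * d
            sabs += abs(d)
            sx += X[k, l]
            sy += Y[k, l]
            sxx += X[k, l] ** 2
            syy += Y[k, l] ** 2
            sxy += X[k, l] * Y[k, l]
            maxd = max(maxd, abs(d))
    N = m * n
    mse = se / N
    out = {
        "mse": mse,
        "psnr": math.inf if mse == 0 else 10 * math.log10(peak ** 2 / mse),
        "snr": math.inf if se == 0 else 10 * math.log10(syy / se),
        "nae": sabs / sx,
        "ncc": sxy / sxx,
        "ad": (sx - sy) / N,
        "md": maxd,
        "sc": sxx / syy,
    }
    mx, my = sx / N, sy / N
    vx = sum((X[k, l] - mx) ** 2 for k in range(m) for l in range(n)) / N
    vy = sum((Y[k, l] - my) ** 2 for k in range(m) for l in range(n)) / N
    cov = sum((X[k, l] - mx) * (Y[k, l] - my)
              for k in range(m) for l in range(n)) / N
    out["ssim"] = ((2 * mx * my + c1) * (2 * cov + c2)
                   / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return out


def auc_pairs(scores, labels):
    """AUC by exhaustive positive/negative pair counting (ties = 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def confusion_bruteforce(tp, fp, tn, fn):
    """The five percentages straight from their defining ratios."""
    def pct(num, den):
        return math.nan if den == 0 else 100.0 * num / den

    return {
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "accuracy": pct(tp + tn, tp + fp + tn + fn),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }
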