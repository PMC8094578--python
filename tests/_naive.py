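"""Independent brute-force oracles used only by the tests.

These are literal, unoptimized transcriptions of the defining formulas —
deliberately sharing no code with the package so they can serve as
independent checks.
"""

import statistics

import numpy as np


def naive_gamma(X, y):
    """Literal transcription of the separability score.

    Per class: covariance of the subsample, eigen-decomposition; per pair:
    d = (||mu2-mu1|| - (d1+d2)) / (sqrt(sum l1) + sqrt(sum l2)) with the
    border distances 1/sqrt(sum mu~_j^2/lambda_j), mu~ = U^{-1} (explicit
    matrix inverse) applied to the unit mean-mean vector.  Assumes all
    eigenvalues strictly positive (random full-rank instances).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    mus, lams, Us = {}, {}, {}
    for k in classes:
        sub = X[y == k]
        n_k = sub.shape[0]
        mu = sub.sum(axis=0) / n_k
        W = np.zeros((X.shape[1], X.shape[1]))
        for row in sub:
            d = row - mu
            W += np.outer(d, d)
        W /= (n_k - 1)
        lam, U = np.linalg.eig(W)
        mus[k], lams[k], Us[k] = mu, np.real(lam), np.real(U)
    total = 0.0
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            k1, k2 = classes[a], classes[b]
            mm = mus[k2] - mus[k1]
            norm = np.sqrt(np.sum(mm ** 2))
            unit = mm / norm
            alpha = np.sqrt(np.sum(lams[k1])) + np.sqrt(np.sum(lams[k2]))
            borders = []
            for k in (k1, k2):
                mu_t = np.linalg.inv(Us[k]) @ unit
                s = sum(mu_t[j] ** 2 / lams[k][j] for j in range(len(mu_t)))
                borders.append(1.0 / np.sqrt(s))
            total += (norm - (borders[0] + borders[1])) / alpha
    return total


def naive_derivative_moments(iv_ms):
    """m_d / sd_d of the order-d successive differences, seconds scale."""
    x = [v / 1000.0 for v in iv_ms]
    out = {}
    for d in range(11):
        cur = list(x)
        for _ in range(d):
            cur = [cur[i + 1] - cur[i] for i in range(len(cur) - 1)]
        out[f"m_{d}"] = statistics.fmean(cur)
        out[f"sd_{d}"] = statistics.stdev(cur)
    return out


def naive_time_domain(iv_ms):
    """Loop-based transcription of the ten time-domain measures (ms scale).

    Convention choices (5-s window rule, 7.8125 ms histogram bins, type-7
    quantiles) mirror the package's documented conventions; the computations
    themselves are written independently.
    """
    iv = list(map(float, iv_ms))
    n = len(iv)
    diffs = [iv[i + 1] - iv[i] for i in range(n - 1)]
    out = {}

    # 5-s windows: accumulate until >= 5000 ms; keep final partial if >= 2
    windows, cur, acc = [], [], 0.0
    for v in iv:
        cur.append(v)
        acc += v
        if acc >= 5000.0:
            windows.append(cur)
            cur, acc = [], 0.0
    if len(cur) >= 2:
        windows.append(cur)
    if len(windows) <= 1:
        out["SDANN"] = 0.0
        out["SDNNidx"] = statistics.stdev(windows[0]) if windows else 0.0
    else:
        out["SDANN"] = statistics.stdev([statistics.fmean(w) for w in windows])
        out["SDNNidx"] = statistics.fmean([statistics.stdev(w) for w in windows])

    out["SDSD"] = statistics.stdev(diffs) if len(diffs) >= 2 else 0.0
    out["SDNN"] = statistics.stdev(iv)
    out["RMSSD"] = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
    out["pNN50"] = 100.0 * sum(1 for d in diffs if abs(d) > 50.0) / len(diffs)
    q1, q3 = np.quantile(np.asarray(iv), [0.25, 0.75])
    out["IRRR"] = float(q3 - q1)

    width = 7.8125
    lo = np.floor(min(iv) / width) * width
    hi = np.ceil(max(iv) / width) * width
    if hi <= lo:
        hi = lo + width
    nbins = int(round((hi - lo) / width))
    counts = [0] * nbins
    for v in iv:
        j = min(int((v - lo) / width), nbins - 1)
        counts[j] += 1
    out["HRV.index"] = n / max(counts)

    # triangular fit: peak fixed at the modal bin centre/height, N/M on edges
    centers = [lo + width * (j + 0.5) for j in range(nbins)]
    edges = [lo + width * j for j in range(nbins + 1)]
    peak = counts.index(max(counts))
    xc, yc = centers[peak], float(max(counts))
    best_err, best_w = float("inf"), 0.0
    for n_edge in edges[: peak + 1]:
        for m_edge in edges[peak + 1:]:
            err = 0.0
            for c, h in zip(centers, counts):
                if n_edge < c <= xc and xc > n_edge:
                    t = yc * (c - n_edge) / (xc - n_edge)
                elif xc < c < m_edge and m_edge > xc:
                    t = yc * (m_edge - c) / (m_edge - xc)
                elif c == xc:
                    t = yc
                else:
                    t = 0.0
                err += (t - h) ** 2
            if err < best_err - 1e-12:
                best_err, best_w = err, m_edge - n_edge
    out["TINN"] = best_w

    out["MADRR"] = statistics.median(abs(d) for d in diffs)
    return out
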