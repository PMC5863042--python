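"""Independent brute-force oracles.

Everything here is written from the defining formulas with explicit Python
loops and no reuse of the package's vectorised code paths, so that agreement
between the two is informative. The mutual-information oracle goes through
the partial-correlation identity I = -1/2 ln(1 - rho_p^2), whereas the
implementation evaluates the three-log entropy expression directly — two
different algebraic routes to the same quantity.
"""

import math

import numpy as np

MI_NORM = 0.5 * (1.0 + math.log(2.0 * math.pi))


def partial3(rho, i, j, l):
    num = rho[j][l] - rho[i][j] * rho[i][l]
    den = math.sqrt((1.0 - rho[i][j] ** 2) * (1.0 - rho[i][l] ** 2))
    return num / den


def oracle_corr_A(rho, mode="all"):
    n = len(rho)
    values, defined = [], []
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            for l in range(j + 1, n):
                if j == i or l == i:
                    continue
                if mode == "positive" and not (
                    rho[i][j] > 0 and rho[i][l] > 0 and rho[j][l] > 0
                ):
                    continue
                if mode == "negative" and not (
                    rho[i][j] < 0 and rho[i][l] < 0 and rho[j][l] < 0
                ):
                    continue
                w = abs(rho[i][j] * rho[i][l])
                if w > 0.0:
                    num += w * abs(partial3(rho, i, j, l))
                den += w
        defined.append(den > 0.0)
        values.append(num / den if den > 0.0 else 0.0)
    return np.array(values), np.array(defined)


def oracle_corr_M(rho, mode="all"):
    n = len(rho)
    values, defined = [], []
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            for l in range(j + 1, n):
                if j == i or l == i:
                    continue
                if mode == "positive" and not (
                    rho[i][j] > 0 and rho[i][l] > 0 and rho[j][l] > 0
                ):
                    continue
                if mode == "negative" and not (
                    rho[i][j] < 0 and rho[i][l] < 0 and rho[j][l] < 0
                ):
                    continue
                w = abs(rho[i][j] * rho[i][l])
                if w > 0.0:
                    p = partial3(rho, i, j, l)
                    num += w * (-0.5 * math.log(1.0 - p * p))
                den += MI_NORM * w
        defined.append(den > 0.0)
        values.append(num / den if den > 0.0 else 0.0)
    return np.array(values), np.array(defined)


def oracle_unweighted(adj):
    n = len(adj)
    values, defined = [], []
    for i in range(n):
        k = sum(adj[i][j] for j in range(n))
        tri = 0
        for j in range(n):
            for l in range(j + 1, n):
                if adj[i][j] and adj[i][l] and adj[j][l]:
                    tri += 1
        defined.append(k >= 2)
        values.append(tri / (k * (k - 1) / 2.0) if k >= 2 else 0.0)
    return np.array(values), np.array(defined)


def oracle_barrat(w):
    n = len(w)
    a = [[1 if w[i][j] > 0 else 0 for j in range(n)] for i in range(n)]
    values, defined = [], []
    for i in range(n):
        k = sum(a[i])
        s = sum(w[i])
        if k < 2 or s == 0:
            defined.append(False)
            values.append(0.0)
            continue
        total = 0.0
        for j in range(n):
            for l in range(n):
                if j == i or l == i:
                    continue
                total += (w[i][j] + w[i][l]) / 2.0 * a[i][j] * a[i][l] * a[j][l]
        defined.append(True)
        values.append(total / (s * (k - 1)))
    return np.array(values), np.array(defined)


def oracle_onnela(w):
    n = len(w)
    wmax = max(max(row) for row in w)
    values, defined = [], []
    for i in range(n):
        k = sum(1 for j in range(n) if w[i][j] > 0)
        if wmax == 0.0 or k < 2:
            defined.append(False)
            values.append(0.0)
            continue
        total = 0.0
        for j in range(n):
            for l in range(n):
                if j == i or l == i:
                    continue
                total += (w[i][j] / wmax * w[i][l] / wmax * w[j][l] / wmax) ** (1.0 / 3.0)
        defined.append(True)
        values.append(total / (k * (k - 1)))
    return np.array(values), np.array(defined)


def oracle_zhang(w):
    n = len(w)
    wmax = max(max(row) for row in w)
    values, defined = [], []
    for i in range(n):
        den = 0.0
        for j in range(n):
            for l in range(n):
                if j == i or l == i or j == l:
                    continue
                den += w[i][j] * w[i][l]
        if wmax == 0.0 or den == 0.0:
            defined.append(False)
            values.append(0.0)
            continue
        num = 0.0
        for j in range(n):
            for l in range(n):
                if j == i or l == i:
                    continue
                num += w[i][j] * w[i][l] * w[j][l]
        defined.append(True)
        values.append(num / (wmax * den))
    return np.array(values), np.array(defined)


def oracle_full_partial(mat):
    """Partial correlation by regressing out all other variables from a pair.

    Works on the covariance/correlation matrix directly: the conditional
    covariance of (i, j) given the rest is S_aa - S_ab S_bb^-1 S_ba, and the
    partial correlation is its normalised off-diagonal.
    """
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rest = [k for k in range(n) if k not in (i, j)]
            s_aa = mat[np.ix_([i, j], [i, j])]
            s_ab = mat[np.ix_([i, j], rest)]
            s_bb = mat[np.ix_(rest, rest)]
            cond = s_aa - s_ab @ np.linalg.solve(s_bb, s_ab.T)
            out[i, j] = out[j, i] = cond[0, 1] / math.sqrt(cond[0, 0] * cond[1, 1])
    return out


def oracle_density_edges(rho, density):
    """Edge set selected by full sort: descending rho, lexicographic ties."""
    n = len(rho)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort(key=lambda p: (-rho[p[0]][p[1]], p[0], p[1]))
    m = math.floor(density * n * (n - 1) / 2)
    return set(pairs[:m])
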