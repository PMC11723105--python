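"""Independent reference computations used only by the tests.

Everything here is written straight from the definitions (loops, no shared
code with the package) so it can serve as an oracle for the production
implementations.
"""

from __future__ import annotations

import numpy as np


def naive_ward(X: np.ndarray) -> np.ndarray:
    """Greedy Ward.D2 agglomeration, recomputing every pairwise merge cost
    from scratch at each step.

    Cost of merging clusters A, B = sqrt(2·|A||B|/(|A|+|B|)) · ||c_A − c_B||
    (the square root of twice the increase in within-cluster sum of
    squares).  Ties broken by lowest cluster ids.  Returns an (n−1)×4 merge
    table [left id, right id, height, size] with new clusters numbered from
    n upward, matching the scipy linkage convention.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    members = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(members) > 1:
        best = None
        ids = sorted(members)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                A, B = X[members[a]], X[members[b]]
                na, nb = len(A), len(B)
                d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(
                    A.mean(axis=0) - B.mean(axis=0))
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append([min(a, b), max(a, b), d, len(members[a]) + len(members[b])])
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return np.asarray(merges)


def straightline_mgidi(X: np.ndarray, lower_mask: np.ndarray) -> np.ndarray:
    """Single-expression recomputation of the genotype-ideotype distance.

    rescale -> correlation -> eigen -> varimax (pairwise Jacobi rotations,
    a different algorithm than the production SVD iteration) -> regression
    scores -> Euclidean distance to the all-best ideotype.  Valid for
    full-rank trait correlation matrices (more genotypes than traits).
    """
    X = np.asarray(X, float)
    lower_mask = np.asarray(lower_mask, bool)
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    resc = (X - lo) / (hi - lo) * 100.0
    resc[:, lower_mask] = 100.0 - resc[:, lower_mask]
    mu, sd = resc.mean(axis=0), resc.std(axis=0, ddof=1)
    Z = (resc - mu) / sd
    R = (Z.T @ Z) / (n - 1)
    lam, V = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    f = max(int(np.sum(lam >= 1.0)), 1)
    L = V[:, :f] * np.sqrt(lam[:f])

    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    for _ in range(500):
        biggest = 0.0
        for i in range(f):
            for j in range(i + 1, f):
                x, y = A[:, i].copy(), A[:, j].copy()
                u, v = x**2 - y**2, 2.0 * x * y
                num = 2.0 * (p * (u * v).sum() - u.sum() * v.sum())
                den = p * ((u**2 - v**2).sum()) - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) > 1e-12:
                    c, s = np.cos(phi), np.sin(phi)
                    A[:, i], A[:, j] = c * x + s * y, -s * x + c * y
                    biggest = max(biggest, abs(phi))
        if biggest < 1e-10:
            break
    Lrot = A * h[:, None]

    B = np.linalg.solve(R, Lrot)
    gamma = Z @ B
    gamma_ideo = ((np.full(p, 100.0) - mu) / sd) @ B
    return np.sqrt(((gamma - gamma_ideo) ** 2).sum(axis=1))


def mahalanobis_lda_predict(X_train, y_train, X_test):
    """Nearest class centroid in pooled-within-class Mahalanobis metric
    (equal priors) — the closed-form linear discriminant rule."""
    X_train = np.asarray(X_train, float)
    X_test = np.atleast_2d(np.asarray(X_test, float))
    classes = np.unique(y_train)
    centroids = np.array([X_train[y_train == c].mean(axis=0) for c in classes])
    pooled = np.zeros((X_train.shape[1], X_train.shape[1]))
    for c, m in zip(classes, centroids):
        D = X_train[y_train == c] - m
        pooled += D.T @ D
    pooled /= X_train.shape[0] - len(classes)
    P = np.linalg.inv(pooled)
    d2 = np.array([[ (x - m) @ P @ (x - m) for m in centroids] for x in X_test])
    return classes[np.argmin(d2, axis=1)]


def anova_by_definition(y: np.ndarray) -> dict[str, float]:
    """Sums of squares for the factorial RCBD (blocks nested in condition),
    computed with explicit loops over the definitional contrasts."""
    y = np.asarray(y, float)
    g, e, r = y.shape
    grand = y.mean()
    ss_g = sum(e * r * (y[i].mean() - grand) ** 2 for i in range(g))
    ss_c = sum(g * r * (y[:, j].mean() - grand) ** 2 for j in range(e))
    ss_b = sum(g * (y[:, j, k].mean() - y[:, j].mean()) ** 2
               for j in range(e) for k in range(r))
    ss_ge = sum(r * (y[i, j].mean() - y[i].mean() - y[:, j].mean() + grand) ** 2
                for i in range(g) for j in range(e))
    ss_tot = ((y - grand) ** 2).sum()
    return {
        "genotype": ss_g, "condition": ss_c, "block(condition)": ss_b,
        "genotype:condition": ss_ge,
        "residual": ss_tot - ss_g - ss_c - ss_b - ss_ge, "total": ss_tot,
    }


def gs_max_transliterated(sd_mm2, p_um, w_um, d=2.82e-5, v=0.0245):
    """Direct transliteration of the anatomical conductance formula."""
    SD = np.asarray(sd_mm2) * 1e6
    a_max = np.pi * (np.asarray(p_um) * 1e-6 / 2.0) ** 2
    l = np.asarray(w_um) * 1e-6 / 2.0
    return (d * SD * a_max) / (1.6 * v * (l + (np.pi / 2.0) * np.sqrt(a_max / np.pi)))
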