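"""Linear max-margin classification kernels for time-resolved decoding.

The solver is dual coordinate descent for the L2-regularized hinge-loss SVM
(the liblinear algorithm for L1-loss SVC), with the bias handled as an
appended constant feature.  With C = 1 and the tolerances used here it
reproduces ``sklearn.svm.LinearSVC(loss="hinge", dual=True)`` to numerical
precision on the small problems this package solves — a property asserted
by the test suite — while avoiding per-call estimator overhead that would
make permutation-null ensembles (10^5–10^7 fits per analysis) impractical.

Multiclass problems use one-vs-one pairwise voting; ties are broken by the
summed pairwise decision values, then by the lowest class index.

Everything here is numba-jitted and deterministic: iteration order is fixed
and no randomness is consumed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DCD_MAX_EPOCHS = 30
DCD_TOL = 1e-3


@njit(cache=True)
def dcd_fit(X, y, C, w, alpha, max_epochs, tol):
    """Dual coordinate descent for min ½|w|² + C Σ max(0, 1 − y_i w·x_i).

    The liblinear schedule: coordinates are visited in a fresh random
    permutation each epoch (deterministic xorshift stream, so fits are
    reproducible), bound variables whose projected gradient violates the
    previous epoch's range are shrunk out of the active set, and the stop
    criterion is the projected-gradient range over a full pass.  The
    converged weight vector is unique regardless of the visiting order.

    ``X`` is (n, d) with any bias column already appended; ``y`` is ±1.
    ``w`` (d,) is a preallocated output; ``alpha`` (n,) is in/out — values
    in [0, C] warm-start the solver (the time-resolved kernel reuses the
    previous bin's solution, whose features differ by one window sample),
    and the initial weight vector is reconstructed from them.
    """
    n, d = X.shape
    for j in range(d):
        w[j] = 0.0
    Q = np.empty(n)
    index = np.empty(n, dtype=np.int64)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        Q[i] = s
        index[i] = i
        if alpha[i] != 0.0:
            ay = alpha[i] * y[i]
            for j in range(d):
                w[j] += ay * X[i, j]

    state = np.uint64(88172645463325252)
    big = 1e30
    active = n
    pgmax_old = big
    pgmin_old = -big
    for _ in range(max_epochs):
        pgmax_new = -big
        pgmin_new = big
        s = 0
        while s < active:
            # xorshift64 draw in [s, active)
            state ^= state << np.uint64(13)
            state ^= state >> np.uint64(7)
            state ^= state << np.uint64(17)
            r = s + int(state % np.uint64(active - s))
            tmp = index[s]
            index[s] = index[r]
            index[r] = tmp
            i = index[s]
            if Q[i] <= 0.0:
                s += 1
                continue
            g = 0.0
            for j in range(d):
                g += w[j] * X[i, j]
            G = y[i] * g - 1.0
            PG = 0.0
            if alpha[i] == 0.0:
                if G > pgmax_old:
                    # shrink: swap out of the active set, revisit slot s
                    active -= 1
                    index[s] = index[active]
                    index[active] = i
                    continue
                if G < 0.0:
                    PG = G
            elif alpha[i] == C:
                if G < pgmin_old:
                    active -= 1
                    index[s] = index[active]
                    index[active] = i
                    continue
                if G > 0.0:
                    PG = G
            else:
                PG = G
            if PG > pgmax_new:
                pgmax_new = PG
            if PG < pgmin_new:
                pgmin_new = PG
            if abs(PG) > 1e-12:
                a_new = alpha[i] - G / Q[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                da = (a_new - alpha[i]) * y[i]
                if da != 0.0:
                    for j in range(d):
                        w[j] += da * X[i, j]
                    alpha[i] = a_new
            s += 1
        if pgmax_new - pgmin_new <= tol:
            if active == n:
                break
            # converged on the shrunk set: re-activate everything and verify
            active = n
            pgmax_old = big
            pgmin_old = -big
        else:
            pgmax_old = pgmax_new if pgmax_new > 0.0 else big
            pgmin_old = pgmin_new if pgmin_new < 0.0 else -big
    return w


@njit(cache=True)
def dcd_gram_fit(K, y, C, alpha, max_epochs, tol):
    """Dual coordinate descent on the Gram matrix with maintained gradients.

    Solves the same box-constrained dual as :func:`dcd_fit` but keeps the
    full gradient vector up to date (an O(n) update only when a dual
    variable moves), which is substantially cheaper than O(d) feature dots
    when there are fewer training pseudo-trials than features.  ``alpha``
    is in/out for warm starting; the weight vector is reconstructed by the
    caller as X^T (alpha * y).
    """
    n = K.shape[0]
    grad = np.empty(n)
    index = np.empty(n, dtype=np.int64)
    for i in range(n):
        s = -1.0
        for j in range(n):
            if alpha[j] != 0.0:
                s += y[i] * y[j] * K[i, j] * alpha[j]
        grad[i] = s
        index[i] = i

    state = np.uint64(88172645463325252)
    big = 1e30
    active = n
    pgmax_old = big
    pgmin_old = -big
    for _ in range(max_epochs):
        pgmax_new = -big
        pgmin_new = big
        s = 0
        while s < active:
            state ^= state << np.uint64(13)
            state ^= state >> np.uint64(7)
            state ^= state << np.uint64(17)
            r = s + int(state % np.uint64(active - s))
            tmp = index[s]
            index[s] = index[r]
            index[r] = tmp
            i = index[s]
            Qii = K[i, i]
            if Qii <= 0.0:
                s += 1
                continue
            G = grad[i]
            PG = 0.0
            if alpha[i] == 0.0:
                if G > pgmax_old:
                    active -= 1
                    index[s] = index[active]
                    index[active] = i
                    continue
                if G < 0.0:
                    PG = G
            elif alpha[i] == C:
                if G < pgmin_old:
                    active -= 1
                    index[s] = index[active]
                    index[active] = i
                    continue
                if G > 0.0:
                    PG = G
            else:
                PG = G
            if PG > pgmax_new:
                pgmax_new = PG
            if PG < pgmin_new:
                pgmin_new = PG
            if abs(PG) > 1e-12:
                a_new = alpha[i] - G / Qii
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                delta = a_new - alpha[i]
                if delta != 0.0:
                    alpha[i] = a_new
                    for k in range(n):
                        grad[k] += delta * y[k] * y[i] * K[k, i]
            s += 1
        if pgmax_new - pgmin_new <= tol:
            if active == n:
                break
            active = n
            pgmax_old = big
            pgmin_old = -big
        else:
            pgmax_old = pgmax_new if pgmax_new > 0.0 else big
            pgmin_old = pgmin_new if pgmin_new < 0.0 else -big
    return alpha


@njit(cache=True)
def _predict_ovo(Gmat, glab, Tmat, d, n_classes, C):
    """Fit all class pairs on ``Gmat`` rows and vote on ``Tmat`` rows.

    Returns predicted class indices for the test rows.  Pairs with an empty
    side are skipped; all-zero votes fall back to the summed-margin score,
    then to the lowest class index.
    """
    ng = Gmat.shape[0]
    nt = Tmat.shape[0]
    votes = np.zeros((nt, n_classes))
    scores = np.zeros((nt, n_classes))
    w = np.empty(d)
    for a in range(n_classes):
        for b in range(a + 1, n_classes):
            na = 0
            nb = 0
            for g in range(ng):
                if glab[g] == a:
                    na += 1
                elif glab[g] == b:
                    nb += 1
            if na == 0 or nb == 0:
                continue
            Xp = np.empty((na + nb, d))
            yp = np.empty(na + nb)
            r = 0
            for g in range(ng):
                if glab[g] == a or glab[g] == b:
                    for j in range(d):
                        Xp[r, j] = Gmat[g, j]
                    yp[r] = 1.0 if glab[g] == a else -1.0
                    r += 1
            alpha = np.zeros(na + nb)
            dcd_fit(Xp, yp, C, w, alpha, DCD_MAX_EPOCHS, DCD_TOL)
            for t in range(nt):
                dec = 0.0
                for j in range(d):
                    dec += w[j] * Tmat[t, j]
                if dec > 0.0:
                    votes[t, a] += 1.0
                else:
                    votes[t, b] += 1.0
                scores[t, a] += dec
                scores[t, b] -= dec
    pred = np.empty(nt, dtype=np.int64)
    for t in range(nt):
        best = 0
        for k in range(1, n_classes):
            if votes[t, k] > votes[t, best] or (
                votes[t, k] == votes[t, best] and scores[t, k] > scores[t, best]
            ):
                best = k
        pred[t] = best
    return pred


@njit(cache=True)
def decode_kernel(
    X,                # (n_trials, n_channels, n_bins) float64
    y,                # (n_trials,) int64 class indices
    fold_of,          # (n_trials,) int64 test-fold assignment
    n_folds,
    member_idx,       # flattened group member trial indices
    m_start,          # (n_groups+1,) member slice bounds per group
    group_label,      # (n_groups,) int64 training label per pseudo-trial
    gf_start,         # (n_folds+1,) group slice bounds per fold
    n_classes,
    radius,
    C,
    standardize,
):
    """Accuracy per (fold, time-bin) for the full windowed OvO analysis.

    Per fold, training pseudo-trials (member means) are formed once over
    the whole epoch and z-scored column-wise; because each feature is an
    absolute (channel, sample) pair, its standardization statistics do not
    depend on which window contains it, so the windowed Gram matrix of the
    pseudo-trials can be maintained incrementally as the window slides
    (add the entering sample's cross-products, drop the leaving one's).
    Each class pair is solved in the dual on that Gram, warm-started from
    the previous bin, and single left-out trials are scored by pairwise
    voting on the reconstructed weight vector.
    """
    n_trials, n_ch, n_bins = X.shape
    acc = np.zeros((n_folds, n_bins))
    n_pairs = n_classes * (n_classes - 1) // 2

    for f in range(n_folds):
        nt = 0
        for i in range(n_trials):
            if fold_of[i] == f:
                nt += 1
        if nt == 0:
            continue
        test_idx = np.empty(nt, dtype=np.int64)
        r = 0
        for i in range(n_trials):
            if fold_of[i] == f:
                test_idx[r] = i
                r += 1
        g0, g1 = gf_start[f], gf_start[f + 1]
        ng = g1 - g0
        glab = group_label[g0:g1]

        # group-averaged training epochs, formed once per fold
        Gz = np.zeros((ng, n_ch, n_bins))
        for gi in range(ng):
            g = g0 + gi
            nm = m_start[g + 1] - m_start[g]
            for mi in range(m_start[g], m_start[g + 1]):
                t = member_idx[mi]
                for c in range(n_ch):
                    for b in range(n_bins):
                        Gz[gi, c, b] += X[t, c, b]
            inv = 1.0 / nm
            for c in range(n_ch):
                for b in range(n_bins):
                    Gz[gi, c, b] *= inv

        # column-wise z-scoring on the pseudo-trials, applied to test trials
        Tz = np.empty((nt, n_ch, n_bins))
        for ti in range(nt):
            t = test_idx[ti]
            for c in range(n_ch):
                for b in range(n_bins):
                    Tz[ti, c, b] = X[t, c, b]
        if standardize:
            for c in range(n_ch):
                for b in range(n_bins):
                    mu = 0.0
                    for gi in range(ng):
                        mu += Gz[gi, c, b]
                    mu /= ng
                    var = 0.0
                    for gi in range(ng):
                        dv = Gz[gi, c, b] - mu
                        var += dv * dv
                    sd = np.sqrt(var / ng)
                    if sd < 1e-12:
                        sd = 1.0
                    inv = 1.0 / sd
                    for gi in range(ng):
                        Gz[gi, c, b] = (Gz[gi, c, b] - mu) * inv
                    for ti in range(nt):
                        Tz[ti, c, b] = (Tz[ti, c, b] - mu) * inv

        # per-pair group rows, fixed across bins within this fold
        pair_a = np.empty(n_pairs, dtype=np.int64)
        pair_b = np.empty(n_pairs, dtype=np.int64)
        pair_rows = np.full((n_pairs, ng), -1, dtype=np.int64)
        pair_n = np.zeros(n_pairs, dtype=np.int64)
        p = 0
        for a in range(n_classes):
            for b in range(a + 1, n_classes):
                pair_a[p] = a
                pair_b[p] = b
                k = 0
                for g in range(ng):
                    if glab[g] == a or glab[g] == b:
                        pair_rows[p, k] = g
                        k += 1
                pair_n[p] = k
                p += 1
        alpha_buf = np.zeros((n_pairs, ng))
        votes = np.empty((nt, n_classes))
        scores = np.empty((nt, n_classes))
        width_max = 2 * radius + 1
        d_max = n_ch * width_max + 1
        w = np.empty(d_max)

        # sliding windowed Gram over all pseudo-trials
        K_win = np.zeros((ng, ng))
        cur_lo = 0
        cur_hi = 0
        for b in range(n_bins):
            lo = b - radius
            if lo < 0:
                lo = 0
            hi = b + radius + 1
            if hi > n_bins:
                hi = n_bins
            for s2 in range(cur_hi, hi):
                for i in range(ng):
                    for k in range(i, ng):
                        add = 0.0
                        for c in range(n_ch):
                            add += Gz[i, c, s2] * Gz[k, c, s2]
                        K_win[i, k] += add
                        if k != i:
                            K_win[k, i] += add
            for s2 in range(cur_lo, lo):
                for i in range(ng):
                    for k in range(i, ng):
                        sub = 0.0
                        for c in range(n_ch):
                            sub += Gz[i, c, s2] * Gz[k, c, s2]
                        K_win[i, k] -= sub
                        if k != i:
                            K_win[k, i] -= sub
            cur_lo = lo
            cur_hi = hi
            width = hi - lo
            d = n_ch * width + 1

            for ti in range(nt):
                for k in range(n_classes):
                    votes[ti, k] = 0.0
                    scores[ti, k] = 0.0
            for p in range(n_pairs):
                npair = pair_n[p]
                if npair == 0:
                    continue
                a = pair_a[p]
                bcls = pair_b[p]
                has_a = False
                has_b = False
                yp = np.empty(npair)
                for k in range(npair):
                    g = pair_rows[p, k]
                    if glab[g] == a:
                        yp[k] = 1.0
                        has_a = True
                    else:
                        yp[k] = -1.0
                        has_b = True
                if not (has_a and has_b):
                    continue
                K = np.empty((npair, npair))
                for i in range(npair):
                    gi = pair_rows[p, i]
                    for k in range(i, npair):
                        gk = pair_rows[p, k]
                        v = K_win[gi, gk] + 1.0   # bias column
                        K[i, k] = v
                        K[k, i] = v
                alpha = alpha_buf[p, :npair]
                dcd_gram_fit(K, yp, C, alpha, DCD_MAX_EPOCHS, DCD_TOL)
                # reconstruct w on the current window
                for j in range(d):
                    w[j] = 0.0
                for i in range(npair):
                    if alpha[i] != 0.0:
                        gi = pair_rows[p, i]
                        ay = alpha[i] * yp[i]
                        for c in range(n_ch):
                            base = c * width
                            for s2 in range(lo, hi):
                                w[base + (s2 - lo)] += ay * Gz[gi, c, s2]
                        w[d - 1] += ay
                for ti in range(nt):
                    dec = w[d - 1]
                    for c in range(n_ch):
                        base = c * width
                        for s2 in range(lo, hi):
                            dec += w[base + (s2 - lo)] * Tz[ti, c, s2]
                    if dec > 0.0:
                        votes[ti, a] += 1.0
                    else:
                        votes[ti, bcls] += 1.0
                    scores[ti, a] += dec
                    scores[ti, bcls] -= dec

            ncorr = 0
            for ti in range(nt):
                best = 0
                for k in range(1, n_classes):
                    if votes[ti, k] > votes[ti, best] or (
                        votes[ti, k] == votes[ti, best]
                        and scores[ti, k] > scores[ti, best]
                    ):
                        best = k
                if best == y[test_idx[ti]]:
                    ncorr += 1
            acc[f, b] = ncorr / nt
    return acc


def sklearn_fit_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, C: float = 1.0):
    """Reference OvO path built on sklearn's liblinear binding.

    Slow (estimator overhead per pair) but independent of the jitted solver;
    used as the cross-check oracle in tests and available as
    ``DecoderSpec(backend="sklearn")``.
    """
    from sklearn.svm import LinearSVC

    classes = np.unique(ytr)
    nt = Xte.shape[0]
    K = int(classes.max()) + 1
    votes = np.zeros((nt, K))
    scores = np.zeros((nt, K))
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            mask = (ytr == a) | (ytr == b)
            yb = np.where(ytr[mask] == a, 1, -1)
            if len(np.unique(yb)) < 2:
                continue
            clf = LinearSVC(
                C=C, loss="hinge", dual=True, fit_intercept=True,
                intercept_scaling=1.0, tol=1e-8, max_iter=200000,
            )
            clf.fit(Xtr[mask], yb)
            dec = Xte @ clf.coef_[0] + clf.intercept_[0]
            votes[:, a] += dec > 0
            votes[:, b] += dec <= 0
            scores[:, a] += dec
            scores[:, b] -= dec
    pred = np.empty(nt, dtype=int)
    for t in range(nt):
        order = np.lexsort((np.arange(K)[::-1], scores[t], votes[t]))
        pred[t] = order[-1]
    return pred
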