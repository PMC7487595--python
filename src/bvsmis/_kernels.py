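"""Compiled numerical kernels for the misclassification-aware interval-censored likelihood.

The log-likelihood for subject i is

    L_i = sum_j D_ij (G_j^{h_i} - G_{j+1}^{h_i}),   h_i = exp(z_i' beta),

where G_j = sum_{k>=j} theta_k is the baseline survival just before interval j
(G_1 = 1, G_{J+2} = 0) and D_ij is the probability of the observed self-report
sequence given the event falls in interval j.  All terms are nonnegative, so the
sum is accumulated directly; a subject with L_i <= 0 makes the log-likelihood -inf.

Profiling theta at fixed beta is an equality-constrained Newton iteration on the
probability simplex (KKT system bordered by the sum-to-one constraint) with
analytic gradient and Hessian, backtracking line search and a lower floor
EPS = 1e-10 on every component.
"""

import numpy as np
from numba import njit

EPS = 1e-10
PROFILE_TOL = 1e-8
PROFILE_MAXITER = 200


@njit(cache=True)
def _survival_tails(theta):
    """G[j] = sum_{k>=j} theta_k, clipped to [EPS, 1]; log G alongside."""
    M = theta.shape[0]
    G = np.empty(M)
    logG = np.empty(M)
    acc = 0.0
    for j in range(M - 1, -1, -1):
        acc += theta[j]
        g = acc
        if g < EPS:
            g = EPS
        if g > 1.0:
            g = 1.0
        G[j] = g
        logG[j] = np.log(g)
    return G, logG


@njit(cache=True)
def loglik_raw(D, h, theta):
    """Sum_i log L_i; -inf as soon as some L_i <= 0."""
    N, M = D.shape
    G, logG = _survival_tails(theta)
    total = 0.0
    for i in range(N):
        hi = h[i]
        Li = 0.0
        prev = np.exp(hi * logG[0])
        for j in range(M):
            nxt = np.exp(hi * logG[j + 1]) if j + 1 < M else 0.0
            Li += D[i, j] * (prev - nxt)
            prev = nxt
        if Li <= 1e-100:  # same floor as loglik_grad_hess
            return -np.inf
        total += np.log(Li)
    return total


@njit(cache=True)
def subject_likelihoods(D, h, theta):
    """Per-subject likelihood contributions L_i (probability scale)."""
    N, M = D.shape
    G, logG = _survival_tails(theta)
    out = np.empty(N)
    for i in range(N):
        hi = h[i]
        Li = 0.0
        prev = np.exp(hi * logG[0])
        for j in range(M):
            nxt = np.exp(hi * logG[j + 1]) if j + 1 < M else 0.0
            Li += D[i, j] * (prev - nxt)
            prev = nxt
        out[i] = Li
    return out


@njit(cache=True)
def loglik_grad_hess(D, h, theta):
    """Log-likelihood with analytic gradient and Hessian w.r.t. theta.

    Uses the differenced coefficients C_ij = D_ij - D_{i,j-1} for which
    L_i = sum_j C_ij G_j^{h_i}, so
        dL_i/dtheta_k   = sum_{j<=k} C_ij h_i G_j^{h_i-1}
        d2L_i/dθ_k dθ_m = sum_{j<=min(k,m)} C_ij h_i (h_i-1) G_j^{h_i-2}.
    Returns (-inf, g, H) when some L_i <= 0 (g, H then meaningless).
    """
    N, M = D.shape
    G, logG = _survival_tails(theta)
    g = np.zeros(M)
    H = np.zeros((M, M))
    V = np.empty(M)
    U = np.empty(M)
    pw = np.empty(M)
    total = 0.0
    for i in range(N):
        hi = h[i]
        for j in range(M):
            pw[j] = np.exp(hi * logG[j])
        Li = 0.0
        for j in range(M):
            nxt = pw[j + 1] if j + 1 < M else 0.0
            Li += D[i, j] * (pw[j] - nxt)
        # 1e-100 floor: below it 1/Li^2 overflows, and such a state is numerically
        # indistinguishable from an impossible observation anyway
        if Li <= 1e-100:
            return -np.inf, g, H
        total += np.log(Li)
        sV = 0.0
        sU = 0.0
        Dprev = 0.0
        for j in range(M):
            Cij = D[i, j] - Dprev
            Dprev = D[i, j]
            q = hi * pw[j] / G[j]
            sV += Cij * q
            sU += Cij * (hi - 1.0) * q / G[j]
            V[j] = sV
            U[j] = sU
        invL = 1.0 / Li
        invL2 = invL * invL
        for k in range(M):
            g[k] += V[k] * invL
            for m in range(M):
                jm = k if k < m else m
                H[k, m] += U[jm] * invL - V[k] * V[m] * invL2
    return total, g, H


@njit(cache=True)
def profile_theta_kernel(D, h, theta0, tol, maxiter):
    """Maximize the log-likelihood over theta on the simplex at fixed h.

    Active-set equality-constrained Newton: coordinates pinned at the EPS floor are
    frozen while the KKT multiplier (mean free-coordinate gradient) says that raising
    them would not improve the objective, and released otherwise.  Damped (LM) Newton
    steps with a backtracking line search drive the free coordinates.

    Returns (theta_star, loglik_star, status): status 1 = converged,
    0 = likelihood -inf even at the start (impossible data under the model),
    2 = iteration/evaluation budget exhausted, 3 = non-finite derivatives.
    """
    M = D.shape[1]
    theta = theta0.copy()
    # project the start into the feasible interior
    s = 0.0
    for k in range(M):
        if theta[k] < EPS:
            theta[k] = EPS
        s += theta[k]
    for k in range(M):
        theta[k] /= s

    l, g, H = loglik_grad_hess(D, h, theta)
    if not np.isfinite(l):
        return theta, -np.inf, 0

    A = np.empty((M + 1, M + 1))
    rhs = np.empty(M + 1)
    d = np.zeros(M)
    free_idx = np.empty(M, dtype=np.int64)
    gnew = g
    Hnew = H
    n_evals = 1
    budget = 600
    status = 2
    for _ in range(maxiter):
        finite = True
        for k in range(M):
            if not np.isfinite(g[k]):
                finite = False
            for m in range(M):
                if not np.isfinite(H[k, m]):
                    finite = False
        if not finite:
            status = 3
            break
        # active set: pinned coordinates stay fixed unless the KKT multiplier
        # (mean gradient over free coordinates) says raising them would help
        lam_kkt = 0.0
        n_interior = 0
        for k in range(M):
            if theta[k] > 1.5 * EPS:
                lam_kkt += g[k]
                n_interior += 1
        if n_interior == 0:
            status = 1
            break
        lam_kkt /= n_interior
        nf = 0
        for k in range(M):
            if theta[k] > 1.5 * EPS or g[k] > lam_kkt + 1e-9 * (1.0 + abs(lam_kkt)):
                free_idx[nf] = k
                nf += 1
        if nf <= 1:
            status = 1  # a single free coordinate cannot move on the simplex
            break
        scale = 1.0
        for a in range(nf):
            if abs(H[free_idx[a], free_idx[a]]) > scale:
                scale = abs(H[free_idx[a], free_idx[a]])
        # Levenberg-Marquardt-damped Newton on the restricted bordered KKT system
        lam = 0.0
        accepted = False
        converged = False
        lnew = l
        cand = theta
        for _trial in range(8):
            ridge = 1e-9 * scale + lam
            # inner active-set refinement: a floored coordinate whose tentative
            # direction is non-positive is re-pinned and the system re-solved
            ok_dir = True
            gd = 0.0
            for _pass in range(M):
                for a in range(nf):
                    ka = free_idx[a]
                    for b in range(nf):
                        A[a, b] = H[ka, free_idx[b]]
                    A[a, a] -= ridge
                    A[a, nf] = 1.0
                    A[nf, a] = 1.0
                    rhs[a] = -g[ka]
                A[nf, nf] = 0.0
                rhs[nf] = 0.0
                sol = np.linalg.solve(A[: nf + 1, : nf + 1], rhs[: nf + 1])
                for k in range(M):
                    d[k] = 0.0
                ok_dir = True
                gd = 0.0
                for a in range(nf):
                    if not np.isfinite(sol[a]):
                        ok_dir = False
                        break
                    d[free_idx[a]] = sol[a]
                    gd += g[free_idx[a]] * sol[a]
                if not ok_dir or nf <= 2:
                    break
                n_drop = 0
                a = 0
                while a < nf:
                    k = free_idx[a]
                    if theta[k] <= 1.5 * EPS and d[k] <= 0.0:
                        free_idx[a] = free_idx[nf - 1]
                        nf -= 1
                        n_drop += 1
                    else:
                        a += 1
                if n_drop == 0 or nf <= 1:
                    break
            if ok_dir and nf <= 1:
                converged = True
                break
            if ok_dir and gd <= 0.0:
                # indefinite restricted Hessian: not an ascent direction, damp harder
                lam = 1e-4 * scale if lam == 0.0 else lam * 30.0
                continue
            if ok_dir:
                # feasibility is enforced by flooring inside the candidate itself,
                # so the line search always starts from the full Newton step
                alpha = 1.0
                for _ls in range(25):
                    if alpha * gd < 0.25 * tol:
                        # negligible attainable improvement left on this direction
                        converged = True
                        break
                    trial_theta = np.empty(M)
                    s = 0.0
                    for k in range(M):
                        c = theta[k] + alpha * d[k]
                        if c < EPS:
                            c = EPS
                        trial_theta[k] = c
                        s += c
                    for k in range(M):
                        trial_theta[k] /= s
                    # fused evaluation: the accepted point's derivatives are reused
                    lnew, gnew, Hnew = loglik_grad_hess(D, h, trial_theta)
                    n_evals += 1
                    if lnew > l:
                        cand = trial_theta
                        accepted = True
                        break
                    alpha *= 0.5
            if accepted or converged:
                break
            lam = 1e-4 * scale if lam == 0.0 else lam * 30.0
        if converged or not accepted:
            status = 1  # not even a damped (near-gradient) step improves: at a maximum
            break
        gain = lnew - l
        theta = cand
        l = lnew
        g = gnew
        H = Hnew
        if gain < tol:
            status = 1
            break
        if n_evals > budget:
            status = 2  # runaway optimization: caller treats as failure
            break
    return theta, l, status
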