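"""Independent reference implementations used only to check the package.

These deliberately avoid the package's closed-form cumulative-hazard path:
the TADA oracle evaluates each individual's hazard integral by numerical
quadrature, and the GLMM oracle integrates the random effect out with
generic adaptive quadrature.
"""
import numpy as np
from scipy import integrate, special, stats


def hazard_fn(t, baseline, params):
    if baseline == "constant":
        return params["lambda0"]
    k, r = params["shape"], params["rate"]
    return stats.gamma.pdf(t, k, scale=1.0 / r) / stats.gamma.sf(t, k, scale=1.0 / r)


def relative_rate_at(t, i, events, a, x_b, s, model_type):
    """R_i just before time t, from the event list (id_index, time)."""
    informed = [j for j, tj in events if tj < t]
    T = sum(a[i, j] for j in informed)
    bx = x_b[i]
    if model_type == "asocial":
        return np.exp(bx)
    if model_type == "additive":
        return s * T + np.exp(bx)
    if model_type == "multiplicative":
        return np.exp(bx) * (s * T + 1.0)
    return s * T + 1.0


def tada_loglik_oracle(events, a, x_b, s, model_type, baseline, params,
                       trial_end, n_ind):
    """Brute-force log-likelihood for one diffusion.

    ``events``: list of (individual index, time); ``a``: association matrix;
    ``x_b``: per-individual ILV linear predictor B.x_i.
    """
    total = 0.0
    times = [t for _, t in events]
    acquired = {i: t for i, t in events}
    for i, t in events:
        lam = hazard_fn(t, baseline, params)
        total += np.log(lam) + np.log(relative_rate_at(t, i, events, a, x_b, s,
                                                       model_type))
    for i in range(n_ind):
        tau = acquired.get(i, trial_end)

        def haz(u, i=i):
            return hazard_fn(u, baseline, params) * relative_rate_at(
                u, i, events, a, x_b, s, model_type)

        pts = sorted({t for t in times if t < tau})
        val, _ = integrate.quad(haz, 0.0, tau, points=pts, limit=200)
        total -= val
    return total


def glmm_loglik_oracle(y, X, groups, beta, alpha, sigma):
    """Marginal gamma-GLMM log-likelihood by dense log-space trapezoid
    integration: a coarse scan locates the integrand mode (which can sit far
    from zero when fixed effects are misspecified), then a fine grid around
    it integrates to high accuracy."""
    eta0 = X @ beta
    total = 0.0
    for g in np.unique(groups):
        idx = groups == g

        def log_integrand(u_grid, idx=idx):
            # (n_u, n_rows) log gamma density at mean exp(eta0 + u)
            mu = np.exp(eta0[idx][None, :] + u_grid[:, None])
            ll = stats.gamma.logpdf(y[idx][None, :], alpha,
                                    scale=mu / alpha).sum(axis=1)
            return ll + stats.norm.logpdf(u_grid, 0, sigma)

        coarse = np.linspace(-10.0, 10.0, 2001)
        lv = log_integrand(coarse)
        u_star = coarse[np.argmax(lv)]
        h = coarse[1] - coarse[0]
        # local curvature -> peak width; fall back to sigma if flat
        j = np.argmax(lv)
        if 0 < j < len(coarse) - 1:
            d2 = (lv[j - 1] - 2 * lv[j] + lv[j + 1]) / h ** 2
            width = 1.0 / np.sqrt(-d2) if d2 < 0 else sigma
        else:
            width = sigma
        fine = np.linspace(u_star - 12 * width, u_star + 12 * width, 8001)
        lf = log_integrand(fine)
        m = lf.max()
        total += m + np.log(np.trapezoid(np.exp(lf - m), fine))
    return total
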