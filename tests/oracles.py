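"""Independent reference implementations used only by the tests.

Everything here is written from the model's distributional definitions with
deliberately different code (scalar loops, scipy.stats frozen distributions)
so that agreement with the package is a genuine two-route check, not a
re-run of the same code.
"""

import math

import numpy as np
from scipy.special import digamma
from scipy.stats import dirichlet, invwishart, wishart


def scalar_log_responsibilities(x, alphas, omegas, Gammas, Psis, sigmas, D=1):
    """Unnormalized log-responsibilities for a single 1-D event, transcribed
    symbol by symbol from the posterior-membership formula.

    All arguments are plain floats / lists of floats (one entry per
    component).
    """
    K = len(alphas)
    asum = sum(alphas)
    out = []
    for k in range(K):
        e_ln_pi = digamma(alphas[k]) - digamma(asum)
        e_ln_det = digamma(sigmas[k] / 2.0) + math.log(2.0) + math.log(Psis[k])
        e_maha = sigmas[k] * ((x - omegas[k]) ** 2 * Psis[k] + Gammas[k] * Psis[k])
        out.append(
            e_ln_pi + 0.5 * e_ln_det - 0.5 * D * math.log(2.0 * math.pi) - 0.5 * e_maha
        )
    return out


def softmax(values):
    mx = max(values)
    ex = [math.exp(v - mx) for v in values]
    s = sum(ex)
    return [e / s for e in ex]


class SingleSampleVB:
    """From-scratch variational fit of the single-sample (M = 1) model.

    Mixture of K Gaussians with priors

    * weights ~ Dirichlet(alpha0),
    * component means ``mu_k ~ N(eta_k, (beta0 I)^-1)`` with
      ``eta_k ~ N(0, (eps0 I)^-1)``,
    * component precisions ``Lambda_k`` Wishart with mean ``Omega_k`` and
      dof sigma0, with ``Omega_k ~ InvWishart(Phi0, nu0)``.

    Everything is computed with explicit per-component loops and
    scipy.stats objects; no code is shared with the package.
    """

    def __init__(self, X, K, alpha0, beta0, sigma0, nu0, eps0=1.0):
        self.X = np.asarray(X, float)
        self.N, self.D = self.X.shape
        self.K = K
        self.alpha0, self.beta0 = alpha0, beta0
        self.sigma0, self.nu0, self.eps0 = sigma0, nu0, eps0
        self.Phi0 = np.eye(self.D)

    def set_initial(self, omega, Psi, sigma, alpha, xi, Gamma, Phi, nu):
        self.omega = [np.array(omega[k], float) for k in range(self.K)]
        self.Psi = [np.array(Psi[k], float) for k in range(self.K)]
        self.sigma = [float(s) for s in sigma]
        self.alpha = [float(a) for a in alpha]
        self.xi = [np.array(xi[k], float) for k in range(self.K)]
        self.Gamma = [np.array(Gamma[k], float) for k in range(self.K)]
        self.Phi = [np.array(Phi[k], float) for k in range(self.K)]
        self.nu = float(nu)
        self.Upsilon = [np.eye(self.D) / (self.eps0 + self.beta0)] * self.K

    # -- one full coordinate sweep, same update order as the package -------

    def sweep(self):
        K, D, N = self.K, self.D, self.N
        # responsibilities
        asum = sum(self.alpha)
        logr = np.empty((N, K))
        for k in range(K):
            e_ln_pi = digamma(self.alpha[k]) - digamma(asum)
            sign, ld = np.linalg.slogdet(self.Psi[k])
            e_ln_det = (
                sum(digamma((self.sigma[k] + 1 - i) / 2.0) for i in range(1, D + 1))
                + D * math.log(2.0) + ld
            )
            for n in range(N):
                d = self.X[n] - self.omega[k]
                maha = self.sigma[k] * (
                    d @ self.Psi[k] @ d + np.trace(self.Gamma[k] @ self.Psi[k])
                )
                logr[n, k] = (
                    e_ln_pi + 0.5 * e_ln_det - 0.5 * D * math.log(2 * math.pi)
                    - 0.5 * maha
                )
        r = np.array([softmax(list(row)) for row in logr])
        self.r = r
        # counts, weights, moments
        self.Nk = [float(r[:, k].sum()) for k in range(K)]
        self.alpha = [self.alpha0 + self.Nk[k] for k in range(K)]
        self.xbar, self.S = [], []
        for k in range(K):
            if self.Nk[k] < 1e-8:
                self.xbar.append(self.xi[k].copy())
                self.S.append(np.zeros((D, D)))
                continue
            xb = sum(r[n, k] * self.X[n] for n in range(N)) / self.Nk[k]
            S = sum(
                r[n, k] * np.outer(self.X[n] - xb, self.X[n] - xb) for n in range(N)
            ) / self.Nk[k]
            self.xbar.append(xb)
            self.S.append(S)
        # precisions
        for k in range(K):
            EOmega_inv = self.nu * np.linalg.inv(self.Phi[k])
            gap = self.xbar[k] - self.omega[k]
            Psi_inv = self.sigma0 * EOmega_inv + self.Nk[k] * (
                self.S[k] + np.outer(gap, gap) + self.Gamma[k]
            )
            self.Psi[k] = np.linalg.inv(Psi_inv)
            self.Psi[k] = 0.5 * (self.Psi[k] + self.Psi[k].T)
        self.sigma = [self.Nk[k] + self.sigma0 for k in range(K)]
        # means
        for k in range(K):
            ELam = self.sigma[k] * self.Psi[k]
            A = self.Nk[k] * ELam + self.beta0 * np.eye(D)
            self.Gamma[k] = np.linalg.inv(A)
            self.omega[k] = self.Gamma[k] @ (
                self.Nk[k] * ELam @ self.xbar[k] + self.beta0 * self.xi[k]
            )
        # prototype means (M = 1)
        denom = self.eps0 + self.beta0
        for k in range(K):
            self.xi[k] = self.beta0 * self.omega[k] / denom
            self.Upsilon[k] = np.eye(D) / denom
        # prototype shapes (M = 1)
        for k in range(K):
            self.Phi[k] = self.Phi0 + self.sigma0 * self.sigma[k] * self.Psi[k]
        self.nu = self.nu0 + self.sigma0

    def elbo(self):
        """Full evidence lower bound via scipy.stats log-densities/entropies."""
        K, D, N = self.K, self.D, self.N
        r = self.r
        val = 0.0
        asum = sum(self.alpha)
        e_ln_pi = [digamma(a) - digamma(asum) for a in self.alpha]
        for k in range(K):
            sign, ld = np.linalg.slogdet(self.Psi[k])
            e_ln_det = (
                sum(digamma((self.sigma[k] + 1 - i) / 2.0) for i in range(1, D + 1))
                + D * math.log(2.0) + ld
            )
            ELam = self.sigma[k] * self.Psi[k]
            # expected log-likelihood + membership prior
            for n in range(N):
                if r[n, k] <= 0:
                    continue
                d = self.X[n] - self.omega[k]
                quad = d @ ELam @ d + np.trace(self.Gamma[k] @ ELam)
                val += r[n, k] * (
                    0.5 * (e_ln_det - D * math.log(2 * math.pi)) - 0.5 * quad
                    + e_ln_pi[k] - math.log(r[n, k])
                )
            # mean prior around prototype, and prototype mean hyper-prior
            gap = self.omega[k] - self.xi[k]
            val += 0.5 * D * math.log(self.beta0 / (2 * math.pi)) - 0.5 * self.beta0 * (
                gap @ gap + np.trace(self.Gamma[k]) + np.trace(self.Upsilon[k])
            )
            val += 0.5 * D * math.log(self.eps0 / (2 * math.pi)) - 0.5 * self.eps0 * (
                self.xi[k] @ self.xi[k] + np.trace(self.Upsilon[k])
            )
            # precision prior: Wishart with mean Omega, dof sigma0, under
            # expectations of q(Lambda) = W(Psi, sigma), q(Omega) = IW(Phi, nu)
            EOmega_inv = self.nu * np.linalg.inv(self.Phi[k])
            sgn, ldPhi = np.linalg.slogdet(self.Phi[k])
            e_ln_det_Omega_inv = (
                sum(digamma((self.nu + 1 - i) / 2.0) for i in range(1, D + 1))
                + D * math.log(2.0) - ldPhi
            )
            from scipy.special import multigammaln
            s0 = self.sigma0
            val += (
                0.5 * s0 * D * (math.log(s0) - math.log(2.0))
                - multigammaln(0.5 * s0, D)
                + 0.5 * s0 * e_ln_det_Omega_inv
                + 0.5 * (s0 - D - 1) * e_ln_det
                - 0.5 * s0 * np.trace(EOmega_inv @ ELam)
            )
            # prototype shape hyper-prior IW(Phi0, nu0)
            val += (
                -0.5 * self.nu0 * D * math.log(2.0) - multigammaln(0.5 * self.nu0, D)
                + 0.5 * (self.nu0 + D + 1) * e_ln_det_Omega_inv
                - 0.5 * np.trace(self.Phi0 @ EOmega_inv)
            )  # |Phi0| = I so its log-det term vanishes
            # entropies of the continuous factors
            val += 0.5 * np.linalg.slogdet(self.Gamma[k])[1] + 0.5 * D * (
                1 + math.log(2 * math.pi)
            )
            val += 0.5 * np.linalg.slogdet(self.Upsilon[k])[1] + 0.5 * D * (
                1 + math.log(2 * math.pi)
            )
            val += wishart(df=self.sigma[k], scale=self.Psi[k]).entropy()
            # inverse-Wishart entropy from -E[ln q] (scipy's entropy() for the
            # inverse-Wishart disagrees with Monte Carlo in this version)
            val += (
                -0.5 * self.nu * ldPhi
                + 0.5 * self.nu * D * math.log(2.0)
                + multigammaln(0.5 * self.nu, D)
                - 0.5 * (self.nu + D + 1.0) * e_ln_det_Omega_inv
                + 0.5 * self.nu * D
            )
        # Dirichlet prior term + entropy
        from scipy.special import gammaln
        val += gammaln(K * self.alpha0) - K * gammaln(self.alpha0)
        val += sum((self.alpha0 - 1.0) * e for e in e_ln_pi)
        val += dirichlet(np.array(self.alpha)).entropy()
        return float(val)


def minimax_assignment(sizes, W):
    """Brute-force optimal maximum per-worker (ceiled) load."""
    import itertools

    M = len(sizes)
    best = None
    for cuts in itertools.combinations(range(1, W), M - 1):
        parts, prev = [], 0
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(W - prev)
        load = max(math.ceil(n / w) for n, w in zip(sizes, parts))
        if best is None or load < best:
            best = load
    return best
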