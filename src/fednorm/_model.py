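"""Log posterior and analytic gradients of the hierarchical model.

The model partially pools per-batch regression coefficients under a
shared Gaussian prior with Gaussian hyperpriors on the prior means and
on the *log* prior spreads. Noise is either homoscedastic per batch,
with the per-batch log noise sd itself pooled hierarchically, or
heteroscedastic, where the noise sd is a softplus of a linear function
of the same basis with its own pooled coefficient vector.

Parameterization is chosen per batch: batches with at least
``center_threshold`` rows are *centered* (the sampler moves theta_i
itself — best when the likelihood is informative), smaller and empty
batches are *non-centered* (theta_i = mu + sd * eps_i with eps ~ N(0,1)
— best when the prior dominates). This mixed scheme keeps the posterior
geometry well conditioned across the extremely unbalanced batch sizes
that multi-site data have.

Everything is Gaussian, so the joint log density and its gradient are
closed form; this module exposes them as a single callable consumed by
the sampler. Rows are pre-sorted by batch so per-batch reductions are
contiguous ``reduceat`` calls.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

LOG2PI = float(np.log(2.0 * np.pi))


def softplus(x):
    return np.logaddexp(0.0, x)


class HBRPosterior:
    """Unnormalized log posterior of the partial-pooling model.

    Parameters
    ----------
    phi : (n, k) design matrix (first column intercept).
    y : (n,) response.
    batch_idx : (n,) integer batch index in ``[0, n_batches)``.
    n_batches : total number of batches (batches with zero rows are
        legal; their parameters are then sampled from the prior).
    hyper : dict of hyperprior arrays with keys
        ``m_mu, s_mu, m_logsd, s_logsd`` (each shape (k,)) and
        ``m_mu_sigma, s_mu_sigma, m_logsd_sigma, s_logsd_sigma``
        (shape (1,) homoscedastic, (k,) heteroscedastic).
    noise_mode : {"homoscedastic", "heteroscedastic"}
    center_threshold : batches with this many rows or more use the
        centered parameterization.
    """

    def __init__(self, phi, y, batch_idx, n_batches, hyper,
                 noise_mode="homoscedastic", center_threshold=10,
                 use_compiled=True):
        phi = np.asarray(phi, dtype=float)
        y = np.asarray(y, dtype=float)
        batch_idx = np.asarray(batch_idx, dtype=np.int64)
        order = np.argsort(batch_idx, kind="stable")
        self.phi = np.ascontiguousarray(phi[order])
        self.y = np.ascontiguousarray(y[order])
        self.bidx = batch_idx[order]
        self.n, self.k = self.phi.shape
        self.B = int(n_batches)
        self.noise_mode = noise_mode
        self.counts = np.bincount(self.bidx, minlength=self.B).astype(float)
        self.cent = self.counts >= center_threshold
        self.ncent = ~self.cent
        self.n_cent = int(self.cent.sum())
        # reduceat over non-empty batches only (their starts are strictly
        # increasing and < n); empty batches contribute zero
        starts = np.searchsorted(self.bidx, np.arange(self.B))
        self._nonempty = self.counts > 0
        self._starts_ne = starts[self._nonempty]
        self.use_compiled = bool(use_compiled and _kernels.HAVE_NUMBA)
        self.ks = 1 if noise_mode == "homoscedastic" else self.k
        self.hyper = {key: np.asarray(val, dtype=float).ravel() for key, val in hyper.items()}
        for key in ("m_mu", "s_mu", "m_logsd", "s_logsd"):
            if self.hyper[key].shape != (self.k,):
                raise ValueError(f"hyperprior field {key} must have length {self.k}")
        for key in ("m_mu_sigma", "s_mu_sigma", "m_logsd_sigma", "s_logsd_sigma"):
            if self.hyper[key].shape != (self.ks,):
                raise ValueError(f"hyperprior field {key} must have length {self.ks}")
        self.dim = 2 * self.k + self.B * self.k + 2 * self.ks + self.B * self.ks

    # -- parameter packing -------------------------------------------------
    def unpack(self, v):
        """Split a flat vector into (a, l, E, c, d, H).

        ``E`` rows hold theta_i itself for centered batches and eps_i
        for non-centered ones (same for ``H`` / the noise block).
        """
        k, B, ks = self.k, self.B, self.ks
        i = 0
        a = v[i:i + k]; i += k
        l = v[i:i + k]; i += k
        E = v[i:i + B * k].reshape(B, k); i += B * k
        c = v[i:i + ks]; i += ks
        d = v[i:i + ks]; i += ks
        H = v[i:i + B * ks].reshape(B, ks); i += B * ks
        return a, l, E, c, d, H

    def batch_params(self, a, l, E, c, d, H):
        """Resolve the per-batch parameters theta (B, k) and the noise
        block (log sigma (B,) homoscedastic / theta_sigma (B, k) het)."""
        theta = np.where(self.cent[:, None], E, a[None, :] + np.exp(l)[None, :] * E)
        noise = np.where(self.cent[:, None], H, c[None, :] + np.exp(d)[None, :] * H)
        return theta, noise

    def _segsum(self, x):
        """Per-batch sums of a (n,) or (n, k) array (rows sorted by batch)."""
        out = np.zeros((self.B,) + x.shape[1:])
        if self.n:
            out[self._nonempty] = np.add.reduceat(x, self._starts_ne, axis=0)
        return out

    # -- joint density -----------------------------------------------------
    def logp_and_grad(self, v):
        h = self.hyper
        a, l, E, c, d, H = self.unpack(v)
        grad = np.empty_like(v)
        ga, gl, gE, gc, gd, gH = self.unpack(grad)  # views into grad
        cent, nc = self.cent, self.ncent

        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            sl = np.exp(l)
            theta, noise = self.batch_params(a, l, E, c, d, H)
            if not self.use_compiled:
                mu = np.einsum("nk,nk->n", self.phi, theta[self.bidx])
                r = self.y - mu

            if self.noise_mode == "homoscedastic":
                lam = noise[:, 0]                          # (B,) log noise sd
                inv_s2 = np.exp(-2.0 * lam)
                if self.use_compiled:
                    G, ssr = _kernels.homoscedastic_accumulate(
                        self.phi, self.y, self.bidx, theta, inv_s2)
                else:
                    ssr = self._segsum(r * r)
                    w = r * inv_s2[self.bidx]
                    G = self._segsum(self.phi * w[:, None])  # (B, k) dll/dtheta_i
                ll = -(self.counts * lam).sum() - 0.5 * (ssr * inv_s2).sum() - 0.5 * self.n * LOG2PI
                dlam = -self.counts + ssr * inv_s2         # (B,) dll/dlambda_i
                Gs = dlam[:, None]
            elif self.use_compiled:
                ll_like, G, Gs = _kernels.heteroscedastic_accumulate(
                    self.phi, self.y, self.bidx, theta, noise)
                ll = ll_like - 0.5 * self.n * LOG2PI
            else:
                s = softplus(np.einsum("nk,nk->n", self.phi, noise[self.bidx]))
                s = np.maximum(s, 1e-300)
                ll = -np.log(s).sum() - 0.5 * ((r / s) ** 2).sum() - 0.5 * self.n * LOG2PI
                w = r / (s * s)
                G = self._segsum(self.phi * w[:, None])
                u = np.einsum("nk,nk->n", self.phi, noise[self.bidx])
                sig_u = 1.0 / (1.0 + np.exp(-u))
                du = sig_u * (-1.0 / s + (r * r) / s**3)
                Gs = self._segsum(self.phi * du[:, None])  # (B, k) dll/dtheta_sigma_i

            # mean block: mixed-parameterization prior terms and gradients
            sd_l = np.exp(d)
            dev = (E - a[None, :]) / sl[None, :]           # centered rows only
            dev_s = (H - c[None, :]) / sd_l[None, :]
            gE[nc] = G[nc] * sl[None, :] - E[nc]
            gE[cent] = G[cent] - dev[cent] / sl[None, :]
            ga[:] = G[nc].sum(axis=0) + (dev[cent] / sl[None, :]).sum(axis=0) - (a - h["m_mu"]) / h["s_mu"] ** 2
            gl[:] = ((G[nc] * E[nc]).sum(axis=0) * sl + (dev[cent] ** 2).sum(axis=0)
                     - self.n_cent - (l - h["m_logsd"]) / h["s_logsd"] ** 2)
            # noise block, same structure
            gH[nc] = Gs[nc] * sd_l[None, :] - H[nc]
            gH[cent] = Gs[cent] - dev_s[cent] / sd_l[None, :]
            gc[:] = (Gs[nc].sum(axis=0) + (dev_s[cent] / sd_l[None, :]).sum(axis=0)
                     - (c - h["m_mu_sigma"]) / h["s_mu_sigma"] ** 2)
            gd[:] = ((Gs[nc] * H[nc]).sum(axis=0) * sd_l + (dev_s[cent] ** 2).sum(axis=0)
                     - self.n_cent - (d - h["m_logsd_sigma"]) / h["s_logsd_sigma"] ** 2)

            lp = (
                ll
                - 0.5 * (((a - h["m_mu"]) / h["s_mu"]) ** 2).sum()
                - 0.5 * (((l - h["m_logsd"]) / h["s_logsd"]) ** 2).sum()
                - 0.5 * (E[nc] ** 2).sum()
                - 0.5 * (dev[cent] ** 2).sum() - self.n_cent * l.sum()
                - 0.5 * (((c - h["m_mu_sigma"]) / h["s_mu_sigma"]) ** 2).sum()
                - 0.5 * (((d - h["m_logsd_sigma"]) / h["s_logsd_sigma"]) ** 2).sum()
                - 0.5 * (H[nc] ** 2).sum()
                - 0.5 * (dev_s[cent] ** 2).sum() - self.n_cent * d.sum()
            )

        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(v)
        return float(lp), grad

    # -- starting point ----------------------------------------------------
    def initial_point(self, rng, jitter=0.02):
        """Data-informed start: pooled least squares for the prior mean,
        pooled residual sd for the noise level, small prior spreads."""
        v = np.zeros(self.dim)
        a, l, E, c, d, H = self.unpack(v)
        if self.n > self.k:
            beta, *_ = np.linalg.lstsq(self.phi, self.y, rcond=None)
            resid = self.y - self.phi @ beta
            s0 = max(float(resid.std()), 1e-3)
        else:
            beta = np.zeros(self.k)
            s0 = 1.0
        a[:] = beta
        l[:] = np.log(0.1 * np.abs(beta) + 0.05)
        E[self.cent] = beta[None, :]
        if self.noise_mode == "homoscedastic":
            c[0] = np.log(s0)
            d[0] = np.log(0.3)
            H[self.cent, 0] = c[0]
        else:
            # softplus(x) ~ x for x >> 0; start the intercept at the pooled sd
            c[0] = s0 if s0 > 1.0 else np.log(np.expm1(s0))
            c[1:] = 0.0
            d[:] = np.log(0.1)
            H[self.cent] = c[None, :]
        return v + jitter * rng.standard_normal(self.dim)
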