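"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained implementation of the dynamic Hamiltonian Monte Carlo
variant that doubles the trajectory until the path starts to turn back
on itself (slice-sampling formulation), with:

* dual averaging of the step size toward a target acceptance statistic
  during warmup,
* windowed estimation of a diagonal inverse mass matrix from warmup
  draws (step-size adaptation restarts after every mass update),
* divergence detection (energy error > 1000 marks the transition
  divergent and prunes the subtree).

The target density is supplied as a single ``logp_and_grad(x)`` callable
returning the joint log density and its gradient; a non-finite density
is treated as a zero-probability barrier.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_nuts", "NUTSResult"]

_DIVERGENCE_THRESHOLD = 1000.0


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "logp_prop", "g_prop", "n_keep", "cont", "alpha", "n_alpha", "diverged",
    )


def _leapfrog(f, q, p, grad, eps, inv_mass):
    p1 = p + 0.5 * eps * grad
    q1 = q + eps * inv_mass * p1
    logp1, grad1 = f(q1)
    p1 = p1 + 0.5 * eps * grad1
    return q1, p1, grad1, logp1


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p * p, inv_mass))


def _no_uturn(q_minus, q_plus, p_minus, p_plus, inv_mass):
    dq = q_plus - q_minus
    return (np.dot(dq, inv_mass * p_minus) >= 0.0) and (np.dot(dq, inv_mass * p_plus) >= 0.0)


def _build_tree(f, q, p, grad, logp, log_u, direction, depth, eps, inv_mass, joint0, rng):
    if depth == 0:
        q1, p1, grad1, logp1 = _leapfrog(f, q, p, grad, direction * eps, inv_mass)
        joint = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
        t = _Tree()
        t.q_minus = t.q_plus = q1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = grad1
        t.q_prop, t.logp_prop, t.g_prop = q1, logp1, grad1
        t.n_keep = int(log_u <= joint)
        t.diverged = (log_u - _DIVERGENCE_THRESHOLD) > joint
        t.cont = not t.diverged
        t.alpha = min(1.0, float(np.exp(min(joint - joint0, 0.0)))) if np.isfinite(joint) else 0.0
        t.n_alpha = 1
        return t

    t = _build_tree(f, q, p, grad, logp, log_u, direction, depth - 1, eps, inv_mass, joint0, rng)
    if t.cont:
        if direction == 1:
            t2 = _build_tree(f, t.q_plus, t.p_plus, t.g_plus, logp, log_u, direction, depth - 1, eps, inv_mass, joint0, rng)
            t.q_plus, t.p_plus, t.g_plus = t2.q_plus, t2.p_plus, t2.g_plus
        else:
            t2 = _build_tree(f, t.q_minus, t.p_minus, t.g_minus, logp, log_u, direction, depth - 1, eps, inv_mass, joint0, rng)
            t.q_minus, t.p_minus, t.g_minus = t2.q_minus, t2.p_minus, t2.g_minus
        total = t.n_keep + t2.n_keep
        if t2.n_keep > 0 and rng.random() < t2.n_keep / total:
            t.q_prop, t.logp_prop, t.g_prop = t2.q_prop, t2.logp_prop, t2.g_prop
        t.n_keep = total
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.diverged = t.diverged or t2.diverged
        t.cont = t2.cont and _no_uturn(t.q_minus, t.q_plus, t.p_minus, t.p_plus, inv_mass)
    return t


def _transition(f, q, logp, grad, eps, inv_mass, max_treedepth, rng):
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    joint0 = logp - _kinetic(p, inv_mass)
    log_u = joint0 - rng.exponential()

    q_minus = q_plus = q
    p_minus = p_plus = p
    g_minus = g_plus = grad
    q_prop, logp_prop, g_prop = q, logp, grad
    n_keep, depth = 1, 0
    diverged = False
    alpha_sum, n_alpha = 0.0, 0

    cont = True
    while cont and depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            t = _build_tree(f, q_plus, p_plus, g_plus, logp, log_u, 1, depth, eps, inv_mass, joint0, rng)
            q_plus, p_plus, g_plus = t.q_plus, t.p_plus, t.g_plus
        else:
            t = _build_tree(f, q_minus, p_minus, g_minus, logp, log_u, -1, depth, eps, inv_mass, joint0, rng)
            q_minus, p_minus, g_minus = t.q_minus, t.p_minus, t.g_minus
        if t.cont and t.n_keep > 0 and rng.random() < min(1.0, t.n_keep / n_keep):
            q_prop, logp_prop, g_prop = t.q_prop, t.logp_prop, t.g_prop
        n_keep += t.n_keep
        alpha_sum += t.alpha
        n_alpha += t.n_alpha
        diverged = diverged or t.diverged
        cont = t.cont and _no_uturn(q_minus, q_plus, p_minus, p_plus, inv_mass)
        depth += 1

    accept_stat = alpha_sum / max(n_alpha, 1)
    return q_prop, logp_prop, g_prop, accept_stat, diverged, depth


def _find_initial_step(f, q, logp, grad, inv_mass, rng):
    eps = 1.0
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    joint0 = logp - _kinetic(p, inv_mass)
    for _ in range(60):  # shrink until the first step is finite
        _, p1, _, logp1 = _leapfrog(f, q, p, grad, eps, inv_mass)
        if np.isfinite(logp1):
            break
        eps *= 0.5
    joint1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
    direction = 1 if (joint1 - joint0) > np.log(0.5) else -1
    for _ in range(60):
        eps *= 2.0**direction
        _, p1, _, logp1 = _leapfrog(f, q, p, grad, eps, inv_mass)
        joint1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return eps


class _DualAveraging:
    def __init__(self, eps0, target, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target, self.gamma, self.t0, self.kappa = target, gamma, t0, kappa
        self.m = 0
        self.h_bar = 0.0
        self.log_eps_bar = 0.0
        self.eps = eps0

    def update(self, accept_stat):
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept_stat)
        log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1.0 - w) * self.log_eps_bar
        self.eps = float(np.exp(log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


def _mass_windows(n_tune, init_buffer=75, term_buffer=None, base_window=25):
    """Iteration indices (exclusive ends) of mass-estimation windows."""
    if term_buffer is None:
        # leave a generous final stretch for step-size re-adaptation under
        # the final metric; hierarchical funnels need it
        term_buffer = max(50, int(0.2 * n_tune))
    if n_tune < init_buffer + term_buffer + base_window:
        return []
    ends = []
    start = init_buffer
    w = base_window
    while True:
        end = start + w
        if end + term_buffer + 2 * w > n_tune:
            end = n_tune - term_buffer
            ends.append(end)
            break
        ends.append(end)
        start = end
        w *= 2
    return ends


class NUTSResult:
    def __init__(self, draws, n_divergent, accept_rate, step_size, inv_mass, treedepth_hits):
        self.draws = draws
        self.n_divergent = n_divergent
        self.accept_rate = accept_rate
        self.step_size = step_size
        self.inv_mass = inv_mass
        self.treedepth_hits = treedepth_hits


def sample_nuts(
    logp_and_grad,
    x0,
    n_tune: int,
    n_draws: int,
    rng,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> NUTSResult:
    """Run one chain; returns the post-warmup draws and diagnostics."""
    rng = np.random.default_rng(rng)
    q = np.asarray(x0, dtype=float).copy()
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")
    inv_mass = np.ones(q.size)

    eps0 = _find_initial_step(logp_and_grad, q, logp, grad, inv_mass, rng)
    da = _DualAveraging(eps0, target_accept)
    windows = _mass_windows(n_tune)
    window_buf: list[np.ndarray] = []

    draws = np.empty((n_draws, q.size))
    n_div = 0
    accept_sum = 0.0
    depth_hits = 0
    eps = da.eps

    for it in range(n_tune + n_draws):
        q, logp, grad, accept_stat, diverged, depth = _transition(
            logp_and_grad, q, logp, grad, eps, inv_mass, max_treedepth, rng
        )
        if it < n_tune:
            da.update(accept_stat)
            eps = da.eps
            if windows:
                window_buf.append(q.copy())
                if it + 1 == windows[0]:
                    buf = np.asarray(window_buf)
                    if len(buf) >= 5:
                        var = buf.var(axis=0, ddof=1)
                        n_w = len(buf)
                        inv_mass = (n_w / (n_w + 5.0)) * var + 1e-3 * (5.0 / (n_w + 5.0))
                        inv_mass = np.maximum(inv_mass, 1e-10)
                    windows.pop(0)
                    window_buf = []
                    # restart step-size adaptation under the new metric
                    eps0 = _find_initial_step(logp_and_grad, q, logp, grad, inv_mass, rng)
                    da = _DualAveraging(eps0, target_accept)
                    eps = da.eps
            if it + 1 == n_tune:
                eps = da.eps_final
        else:
            j = it - n_tune
            draws[j] = q
            n_div += int(diverged)
            accept_sum += accept_stat
            depth_hits += int(depth >= max_treedepth)

    return NUTSResult(
        draws=draws,
        n_divergent=n_div,
        accept_rate=accept_sum / max(n_draws, 1),
        step_size=eps,
        inv_mass=inv_mass,
        treedepth_hits=depth_hits,
    )
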