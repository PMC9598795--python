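"""Subspace state-space identification (N4SID) and model simulation.

Identifies a discrete-time innovation-form state-space model

    x(t+1) = A x(t) + B u(t) + K e(t),   x(0) = 0
    y(t)   = C x(t) + e(t)               (D = 0, no feedthrough)

from input-output records via the oblique-projection subspace method:
block-Hankel matrices of past/future data, oblique projection of future
outputs onto past data along future inputs, SVD truncation to the model
order, least squares for (A, C) on the state-shift equations, a
simulation-error linear least squares for B with D constrained to zero,
and the steady-state Kalman gain K from the residual covariances through
the discrete algebraic Riccati equation.

The temperature estimator uses a 4th-order model with inputs
(V, sigma, dZ) and outputs (dT4, dT10) sampled at the 1 s burst period;
the identification code itself is dimension-agnostic.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = ["SSModel", "IdentificationDataset", "build_block_hankel",
           "n4sid_fit", "simulate_ss", "predict_ss", "save_model",
           "load_model"]


@dataclass
class SSModel:
    """Discrete-time innovation-form state-space model (D = 0)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    K: np.ndarray
    ts: float = 1.0
    input_names: tuple[str, ...] = ()
    output_names: tuple[str, ...] = ()
    input_scale: tuple[float, ...] = ()
    stability_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.B.shape[0] != n or self.C.shape[1] != n:
            raise ValueError("B/C dimensions inconsistent with A")
        if self.K.shape != (n, self.C.shape[0]):
            raise ValueError("K must be n x p")
        if not self.input_names:
            self.input_names = tuple(f"u{k}" for k in range(self.n_inputs))
        if not self.output_names:
            self.output_names = tuple(f"y{k}" for k in range(self.n_outputs))
        if not self.input_scale:
            self.input_scale = (1.0,) * self.n_inputs
        rho = self.spectral_radius
        if rho > 1.0 + self.stability_tol:
            warnings.warn(f"identified A is unstable (spectral radius "
                          f"{rho:.6f})", stacklevel=2)

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    @property
    def D(self) -> np.ndarray:
        return np.zeros((self.n_outputs, self.n_inputs))

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))

    @property
    def n_params(self) -> int:
        """Free parameters: entries of A, B, C and K (D fixed at zero)."""
        n, m, p = self.order, self.n_inputs, self.n_outputs
        return n * n + n * m + p * n + n * p

    def markov_parameters(self, count: int) -> np.ndarray:
        """Impulse-response matrices [C A^k B for k = 0..count-1]."""
        out = np.empty((count, self.n_outputs, self.n_inputs))
        ab = self.B.copy()
        for k in range(count):
            out[k] = self.C @ ab
            ab = self.A @ ab
        return out

    def to_continuous(self) -> tuple[np.ndarray, np.ndarray]:
        """Continuous-time (A_c, B_c) equivalent under zero-order hold,
        via the matrix logarithm of the augmented transition matrix."""
        n, m = self.order, self.n_inputs
        aug = np.eye(n + m)
        aug[:n, :n] = self.A
        aug[:n, n:] = self.B
        log_aug = scipy.linalg.logm(aug) / self.ts
        return np.real(log_aug[:n, :n]), np.real(log_aug[:n, n:])


@dataclass
class IdentificationDataset:
    """Input-output experiments on a common sample time.

    Each experiment is a pair (u: T x m, y: T x p); ``labels`` optionally
    names them (condition/replicate) for reporting.
    """

    experiments: list[tuple[np.ndarray, np.ndarray]]
    ts: float = 1.0
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError("dataset must contain at least one experiment")
        exps = []
        for u, y in self.experiments:
            u = np.atleast_2d(np.asarray(u, dtype=float))
            y = np.atleast_2d(np.asarray(y, dtype=float))
            if u.shape[0] != y.shape[0]:
                raise ValueError("u and y must have equal length")
            exps.append((u, y))
        m = exps[0][0].shape[1]
        p = exps[0][1].shape[1]
        if any(u.shape[1] != m or y.shape[1] != p for u, y in exps):
            raise ValueError("inconsistent channel counts across experiments")
        self.experiments = exps
        if self.labels and len(self.labels) != len(exps):
            raise ValueError("labels must match the number of experiments")

    @property
    def n_inputs(self) -> int:
        return self.experiments[0][0].shape[1]

    @property
    def n_outputs(self) -> int:
        return self.experiments[0][1].shape[1]

    @property
    def n_samples(self) -> int:
        return sum(u.shape[0] for u, _ in self.experiments)


def build_block_hankel(series: np.ndarray, block_rows: int) -> np.ndarray:
    """Block-Hankel matrix with 2*block_rows block rows.

    For a T x c series, block row k (k = 0..2i-1) holds the c channels of
    samples k..k+j-1 where j = T - 2i + 1 columns.  Multi-experiment data
    must be Hankelized per experiment and concatenated column-wise so no
    window spans an experiment boundary.
    """
    s = np.atleast_2d(np.asarray(series, dtype=float))
    if s.shape[0] == 1 and s.shape[1] > 1:
        s = s.T
    t, c = s.shape
    i2 = 2 * block_rows
    j = t - i2 + 1
    if j < 1:
        raise ValueError(
            f"series of length {t} too short for block_rows={block_rows}; "
            f"need at least {i2} samples")
    h = np.empty((i2 * c, j))
    for k in range(i2):
        h[k * c:(k + 1) * c, :] = s[k:k + j, :].T
    return h


def _oblique_projection(yf, wp, uf):
    """Project the rows of yf onto the row space of wp along that of uf."""
    stacked = np.vstack([wp, uf])
    coef, *_ = np.linalg.lstsq(stacked.T, yf.T, rcond=None)
    lw = coef[:wp.shape[0]].T
    return lw @ wp


def _estimate_b_by_simulation(a, c, dataset: IdentificationDataset):
    """Least-squares B (D = 0, x(0) = 0) minimizing the simulation error.

    The output is linear in the entries of B: each unit entry e_r e_q^T
    contributes the convolution of input channel q with the impulse
    response C A^(t-1) e_r.  Exact in the noiseless case.
    """
    n = a.shape[0]
    p = c.shape[0]
    t_max = max(u.shape[0] for u, _ in dataset.experiments)
    # h[r] has shape (t_max, p): response at lag t to a unit state e_r
    h = np.zeros((n, t_max, p))
    x = np.eye(n)
    for t in range(1, t_max):
        x = a @ x if t > 1 else x
        h[:, t, :] = (c @ x).T
    m = dataset.n_inputs
    cols, targets = [], []
    for u, y in dataset.experiments:
        t_len = u.shape[0]
        phi = np.empty((t_len * p, n * m))
        for r in range(n):
            for q in range(m):
                resp = np.empty((t_len, p))
                for ch in range(p):
                    resp[:, ch] = np.convolve(u[:, q], h[r, :t_len, ch])[:t_len]
                phi[:, r * m + q] = resp.ravel()
        cols.append(phi)
        targets.append(y.ravel())
    design = np.vstack(cols)
    rhs = np.concatenate(targets)
    b_vec, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return b_vec.reshape(n, m)


def _clip_spectrum(a, radius: float):
    """Reflect eigenvalues outside ``radius`` back onto that circle.

    Used to start the simulation-focused refinement from a stable point;
    returns ``a`` unchanged when already inside."""
    ev, vec = np.linalg.eig(a)
    outside = np.abs(ev) > radius
    if not outside.any():
        return a
    ev = ev.copy()
    ev[outside] = ev[outside] / np.abs(ev[outside]) * radius
    try:
        return np.real(vec @ np.diag(ev) @ np.linalg.inv(vec))
    except np.linalg.LinAlgError:
        return a * (radius / np.max(np.abs(np.linalg.eigvals(a))))


def _sim_sens_batch(a, b, c, us):
    """Batched simulation with parameter sensitivities.

    ``us`` is (E, T, m) for E equal-length experiments.  Returns outputs
    (E, T, l) and the Jacobian (E, T, l, P) with respect to the packed
    parameters (A row-major, then B, then C).
    """
    n, m = b.shape
    l = c.shape[0]
    e_cnt, t_len, _ = us.shape
    n_a, n_b = n * n, n * m
    p_tot = n_a + n_b + l * n
    ys = np.empty((e_cnt, t_len, l))
    jac = np.zeros((e_cnt, t_len, l, p_tot))
    x = np.zeros((e_cnt, n))
    s = np.zeros((e_cnt, n, n_a + n_b))
    ar = np.arange(n)
    pt = np.zeros((e_cnt, n, n_a + n_b))
    pt_a = pt[:, :, :n_a].reshape(e_cnt, n, n, n)
    pt_b = pt[:, :, n_a:].reshape(e_cnt, n, n, m)
    for t in range(t_len):
        ys[:, t] = x @ c.T
        jac[:, t, :, :n_a + n_b] = np.einsum("kj,ejp->ekp", c, s)
        for k in range(l):
            jac[:, t, k, n_a + n_b + k * n:n_a + n_b + (k + 1) * n] = x
        pt_a[:, ar, ar, :] = x[:, None, :]
        pt_b[:, ar, ar, :] = us[:, t][:, None, :]
        s = np.einsum("ij,ejp->eip", a, s) + pt
        x = x @ a.T + us[:, t] @ b.T
    return ys, jac


def _refine_simulation(a, b, c, dataset: IdentificationDataset,
                       max_iter: int = 80, tol: float = 1e-10,
                       rho_cap: float = 1.05):
    """Gauss-Newton (Levenberg-damped) minimization of the simulation
    error over (A, B, C), each output channel weighted by the inverse of
    its signal norm so every experiment and depth counts comparably in
    the normalized-fit sense.  Expects inputs already scaled."""
    groups: dict[int, list[int]] = {}
    for idx, (u, _) in enumerate(dataset.experiments):
        groups.setdefault(u.shape[0], []).append(idx)
    batches = []
    for t_len, idxs in groups.items():
        us = np.stack([dataset.experiments[i][0] for i in idxs])
        ys = np.stack([dataset.experiments[i][1] for i in idxs])
        w = np.empty((len(idxs), ys.shape[2]))
        for k in range(len(idxs)):
            norms = np.linalg.norm(ys[k] - ys[k].mean(axis=0), axis=0)
            w[k] = 1.0 / np.maximum(norms, 1e-12 + 1e-9 * np.abs(ys[k]).max())
        batches.append((us, ys, w))
    n, m = b.shape
    l = c.shape[0]
    n_a, n_b = n * n, n * m

    def pack(a_, b_, c_):
        return np.concatenate([a_.ravel(), b_.ravel(), c_.ravel()])

    def unpack(p):
        return (p[:n_a].reshape(n, n), p[n_a:n_a + n_b].reshape(n, m),
                p[n_a + n_b:].reshape(l, n))

    def evaluate(p, need_jac):
        a_, b_, c_ = unpack(p)
        if np.max(np.abs(np.linalg.eigvals(a_))) > rho_cap:
            return None, None
        res, jacs = [], []
        for us, ys_ref, w in batches:
            if need_jac:
                ys, jac = _sim_sens_batch(a_, b_, c_, us)
                jacs.append((jac * w[:, None, :, None]
                             ).reshape(-1, jac.shape[-1]))
            else:
                ys = np.stack([_simulate(a_, b_, c_, us[k])
                               for k in range(us.shape[0])])
            res.append(((ys - ys_ref) * w[:, None, :]).ravel())
        r = np.concatenate(res)
        return r, (np.vstack(jacs) if need_jac else None)

    p = pack(a, b, c)
    r, jac = evaluate(p, True)
    if r is None:
        return a, b, c
    cost = 0.5 * float(r @ r)
    lam = 1e-4
    for _ in range(max_iter):
        jtj = jac.T @ jac
        jtr = jac.T @ r
        improved = False
        for _ in range(12):
            try:
                step = np.linalg.solve(jtj + lam * np.diag(np.diag(jtj))
                                       + 1e-12 * np.eye(jtj.shape[0]), -jtr)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            r_new, _ = evaluate(p + step, False)
            if r_new is not None:
                cost_new = 0.5 * float(r_new @ r_new)
                if cost_new < cost:
                    p = p + step
                    rel = (cost - cost_new) / max(cost, 1e-300)
                    cost = cost_new
                    lam = max(lam / 3, 1e-12)
                    improved = True
                    if rel < tol:
                        return unpack(p)
                    break
            lam *= 10
        if not improved:
            break
        r, jac = evaluate(p, True)
    return unpack(p)


def _simulate(a, b, c, u):
    x = np.zeros(a.shape[0])
    y = np.empty((u.shape[0], c.shape[0]))
    for t in range(u.shape[0]):
        y[t] = c @ x
        x = a @ x + b @ u[t]
    return y


def n4sid_fit(data: IdentificationDataset, order: int = 4,
              horizon: int = 10,
              input_scale: tuple[float, ...] | None = None,
              input_names: tuple[str, ...] = (),
              output_names: tuple[str, ...] = (),
              refine: bool = False) -> SSModel:
    """Identify an innovation-form state-space model by N4SID.

    ``horizon`` is the number of block rows i of the past/future Hankel
    partitions (must exceed the model order).  ``input_scale`` rescales
    input channels during the regression for conditioning; the returned
    B is folded back to physical units.  With ``refine`` the subspace
    estimate of (A, B, C) seeds a simulation-focused Gauss-Newton pass
    (output channels weighted by inverse signal norm), the multi-step
    prediction-error polish appropriate when the model is deployed in
    pure simulation.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if horizon <= order:
        raise ValueError("horizon (block rows) must exceed the model order")
    m, l = data.n_inputs, data.n_outputs
    need = 10 * order * (order + m + l)
    if data.n_samples < need:
        raise ValueError(f"dataset has {data.n_samples} samples; "
                         f"subspace identification needs >= {need}")
    scale = np.ones(m) if input_scale is None else np.asarray(input_scale,
                                                              dtype=float)
    if scale.shape != (m,) or np.any(scale <= 0):
        raise ValueError("input_scale must be m positive factors")

    i = horizon
    u_hank, y_hank = [], []
    for u, y in data.experiments:
        if u.shape[0] < 2 * (i + 1):
            raise ValueError(
                f"experiment of length {u.shape[0]} too short for "
                f"horizon {i}; need >= {2 * (i + 1)} samples")
        u_hank.append(build_block_hankel(u * scale, i + 1))
        y_hank.append(build_block_hankel(y, i + 1))
    uh = np.hstack(u_hank)  # 2(i+1) m  x  j
    yh = np.hstack(y_hank)

    def ublk(a, b):
        return uh[a * m:b * m]

    def yblk(a, b):
        return yh[a * l:b * l]

    # partitions at boundary i and i+1 (the shifted problem)
    wp = np.vstack([ublk(0, i), yblk(0, i)])
    uf = ublk(i, 2 * i + 2)
    yf = yblk(i, 2 * i + 2)
    wp_plus = np.vstack([ublk(0, i + 1), yblk(0, i + 1)])
    uf_minus = ublk(i + 1, 2 * i + 2)
    yf_minus = yblk(i + 1, 2 * i + 2)

    o_i = _oblique_projection(yf, wp, uf)
    u_svd, s, _ = np.linalg.svd(o_i, full_matrices=False)
    if order > np.sum(s > max(1e-10 * s[0], 1e-300)):
        warnings.warn(
            f"requested order {order} exceeds the {int(np.sum(s > 1e-10 * s[0]))} "
            f"numerically significant singular values; proceeding",
            stacklevel=2)
    gamma = u_svd[:, :order] * np.sqrt(s[:order])
    o_im1 = _oblique_projection(yf_minus, wp_plus, uf_minus)
    gamma_up = gamma[:-l]

    x_i = np.linalg.pinv(gamma) @ o_i
    x_ip1 = np.linalg.pinv(gamma_up) @ o_im1
    u_ii = ublk(i, i + 1)
    y_ii = yblk(i, i + 1)

    # state-shift least squares with D constrained to zero
    zx = np.vstack([x_i, u_ii])
    ab, res_rank = np.linalg.lstsq(zx.T, x_ip1.T, rcond=None)[:2]
    ab = ab.T
    a_mat, b_raw = ab[:, :order], ab[:, order:]
    c_mat = np.linalg.lstsq(x_i.T, y_ii.T, rcond=None)[0].T

    # innovation covariances -> steady-state Kalman gain
    j = x_i.shape[1]
    rho_w = x_ip1 - a_mat @ x_i - b_raw @ u_ii
    rho_v = y_ii - c_mat @ x_i
    qq = rho_w @ rho_w.T / j
    rr = rho_v @ rho_v.T / j
    ss = rho_w @ rho_v.T / j
    k_mat = np.zeros((order, l))
    if np.trace(rr) > 1e-12 * max(1.0, float(np.mean(y_ii ** 2))):
        try:
            p_mat = scipy.linalg.solve_discrete_are(
                a_mat.T, c_mat.T, qq, rr, s=ss)
            k_mat = np.linalg.solve(
                (c_mat @ p_mat @ c_mat.T + rr).T,
                (a_mat @ p_mat @ c_mat.T + ss).T).T
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
            warnings.warn("Riccati solve for the Kalman gain failed; "
                          "setting K = 0", stacklevel=2)

    # refine B against the simulation error (x0 = 0), exact for
    # noiseless data and better matched to the simulation-fit metric
    scaled = IdentificationDataset(
        [(u * scale, y) for u, y in data.experiments], ts=data.ts)
    b_mat = _estimate_b_by_simulation(a_mat, c_mat, scaled)
    if refine:
        a0 = _clip_spectrum(a_mat, 0.999)
        if a0 is not a_mat:
            b_mat = _estimate_b_by_simulation(a0, c_mat, scaled)
        a_mat, b_mat, c_mat = _refine_simulation(a0, b_mat, c_mat, scaled)

    b_phys = b_mat * scale[None, :]
    return SSModel(A=a_mat, B=b_phys, C=c_mat, K=k_mat, ts=data.ts,
                   input_names=tuple(input_names), output_names=tuple(output_names),
                   input_scale=tuple(scale))


def simulate_ss(model: SSModel, u: np.ndarray) -> np.ndarray:
    """Simulate y(t) = C x(t) with x(t+1) = A x(t) + B u(t), x(0) = 0.

    This is the deployment mode: no temperature measurements are used.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[1] != model.n_inputs:
        raise ValueError(f"u has {u.shape[1]} channels; model expects "
                         f"{model.n_inputs}")
    t_len = u.shape[0]
    y = np.empty((t_len, model.n_outputs))
    x = np.zeros(model.order)
    for t in range(t_len):
        y[t] = model.C @ x
        x = model.A @ x + model.B @ u[t]
    return y


def predict_ss(model: SSModel, u: np.ndarray,
               y_meas: np.ndarray) -> np.ndarray:
    """One-step-ahead predictor using the innovation gain:
    x(t+1) = (A - K C) x(t) + B u(t) + K y_meas(t), y_hat(t) = C x(t)."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    y_meas = np.atleast_2d(np.asarray(y_meas, dtype=float))
    if u.shape[0] != y_meas.shape[0]:
        raise ValueError("u and y_meas must be aligned in time")
    if y_meas.shape[1] != model.n_outputs:
        raise ValueError("y_meas channel count mismatch")
    a_cl = model.A - model.K @ model.C
    t_len = u.shape[0]
    y_hat = np.empty((t_len, model.n_outputs))
    x = np.zeros(model.order)
    for t in range(t_len):
        y_hat[t] = model.C @ x
        x = a_cl @ x + model.B @ u[t] + model.K @ y_meas[t]
    return y_hat


def save_model(model: SSModel, path) -> None:
    """Write the model to JSON (row-major matrices plus metadata)."""
    payload = {
        "A": model.A.tolist(), "B": model.B.tolist(), "C": model.C.tolist(),
        "D": model.D.tolist(), "K": model.K.tolist(),
        "order": model.order, "ts": model.ts,
        "input_names": list(model.input_names),
        "output_names": list(model.output_names),
        "input_scale": list(model.input_scale),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> SSModel:
    with open(path) as fh:
        payload = json.load(fh)
    if np.any(np.asarray(payload.get("D", 0.0)) != 0):
        raise ValueError("model file has nonzero feedthrough D")
    return SSModel(A=np.asarray(payload["A"]), B=np.asarray(payload["B"]),
                   C=np.asarray(payload["C"]), K=np.asarray(payload["K"]),
                   ts=float(payload.get("ts", 1.0)),
                   input_names=tuple(payload.get("input_names", ())),
                   output_names=tuple(payload.get("output_names", ())),
                   input_scale=tuple(payload.get("input_scale", ())))
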