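"""Compiled training kernels for the MLP relaxometry estimators.

The multilayer perceptrons are small (two hidden layers), the batch size
is small (128), and training runs on a single CPU, so the whole
epoch loop -- forward pass, backpropagation, Adam update, and for the
physics-informed loss the analytic bSSFP signal pipeline -- is compiled
with numba.  The physics-informed loss gradient with respect to the two
or three predicted parameters is obtained by central finite differences
of the feature residual, then chained into the network backpropagation.

Everything here is an implementation detail of :mod:`pcbssfp.nn`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32


@njit(cache=True, fastmath=True)
def _forward(X, W1, b1, W2, b2, W3, b3):
    a1 = np.maximum(np.dot(X, W1) + b1, F32(0.0))
    a2 = np.maximum(np.dot(a1, W2) + b2, F32(0.0))
    z = np.dot(a2, W3) + b3
    s = 1.0 / (1.0 + np.exp(-z))
    return a1, a2, s.astype(F32)


def forward(X, params):
    """Sigmoid-layer outputs in (0, 1) for a float32 feature batch."""
    W1, b1, W2, b2, W3, b3 = params
    return _forward(np.ascontiguousarray(X, dtype=F32), W1, b1, W2, b2, W3, b3)[2]


@njit(cache=True, fastmath=True)
def _adam(p, g, m, v, lr, c1, c2):
    pf = p.ravel()
    gf = g.ravel()
    for i in range(pf.size):
        gi = gf[i]
        m[i] = 0.9 * m[i] + 0.1 * gi
        v[i] = 0.999 * v[i] + 0.001 * gi * gi
        pf[i] -= lr * (m[i] / c1) / (np.sqrt(v[i] / c2) + 1e-8)


@njit(cache=True, fastmath=True)
def _backprop_update(Xb, a1, a2, s, d, W1, b1, W2, b2, W3, b3, ms, vs, lr, ts):
    """Backpropagate output-layer gradient ``d`` (already through the
    sigmoid) and apply one Adam step.  ``ms``/``vs`` are flat moment
    buffers in the order (W1, b1, W2, b2, W3, b3)."""
    g5 = np.dot(a2.T, d)
    g6 = d.sum(0)
    da2 = np.dot(d, W3.T)
    da2 = np.where(a2 > 0, da2, F32(0.0))
    g3 = np.dot(a1.T, da2)
    g4 = da2.sum(0)
    da1 = np.dot(da2, W2.T)
    da1 = np.where(a1 > 0, da1, F32(0.0))
    g1 = np.dot(Xb.T, da1)
    g2 = da1.sum(0)
    c1 = 1.0 - 0.9 ** ts
    c2 = 1.0 - 0.999 ** ts
    _adam(W1, g1, ms[0], vs[0], lr, c1, c2)
    _adam(b1, g2, ms[1], vs[1], lr, c1, c2)
    _adam(W2, g3, ms[2], vs[2], lr, c1, c2)
    _adam(b2, g4, ms[3], vs[3], lr, c1, c2)
    _adam(W3, g5, ms[4], vs[4], lr, c1, c2)
    _adam(b3, g6, ms[5], vs[5], lr, c1, c2)


@njit(cache=True, fastmath=True)
def _features_batch(t1, t2, b1, theta, tr, te, alpha_rad, phi, complex_layout, out):
    """Feature pipeline for a parameter batch: simulate the pc-bSSFP
    signal, remove the average (F0) phase, extract modes (F_-1, F_0, F_1),
    arrange the layout and Euclidean-normalize.  ``out`` is (n, 3) or
    (n, 5) float64."""
    n = t1.shape[0]
    npc = phi.shape[0]
    for i in range(n):
        a = alpha_rad * b1[i]
        e1 = np.exp(-tr / t1[i])
        e2 = np.exp(-tr / t2[i])
        sin_a = np.sin(a)
        cos_a = np.cos(a)
        c = e2 * (e1 - 1.0) * (1.0 + cos_a)
        d = (1.0 - e1 * cos_a) - (e1 - cos_a) * e2 * e2
        amp = (1.0 - e1) * sin_a * np.exp(-te / t2[i])
        # global phase e^{i theta te/tr} cancels in average-phase removal
        sr = np.empty(npc)
        si = np.empty(npc)
        mr = 0.0
        mi = 0.0
        for j in range(npc):
            psi = theta[i] - phi[j]
            cp = np.cos(psi)
            sp = np.sin(psi)
            den = amp / (c * cp + d)
            vr = (1.0 - e2 * cp) * den
            vi = (e2 * sp) * den
            sr[j] = vr
            si[j] = vi
            mr += vr
            mi += vi
        mr /= npc
        mi /= npc
        mag = np.sqrt(mr * mr + mi * mi)
        if mag > 0.0:
            cr = mr / mag
            ci = -mi / mag
        else:
            cr = 1.0
            ci = 0.0
        # rotate by -angle(mean) and accumulate the three lowest modes
        fm1r = 0.0
        fm1i = 0.0
        f0r = 0.0
        fp1r = 0.0
        fp1i = 0.0
        for j in range(npc):
            vr = sr[j] * cr - si[j] * ci
            vi = sr[j] * ci + si[j] * cr
            cph = np.cos(phi[j])
            sph = np.sin(phi[j])
            # F_-1: kernel e^{+i phi}; F_+1: kernel e^{-i phi}
            fm1r += vr * cph - vi * sph
            fm1i += vi * cph + vr * sph
            f0r += vr
            fp1r += vr * cph + vi * sph
            fp1i += vi * cph - vr * sph
        fm1r /= npc
        fm1i /= npc
        f0r /= npc
        fp1r /= npc
        fp1i /= npc
        if complex_layout:
            nrm = np.sqrt(
                fm1r * fm1r + f0r * f0r + fp1r * fp1r + fm1i * fm1i + fp1i * fp1i
            )
            out[i, 0] = fm1r / nrm
            out[i, 1] = f0r / nrm
            out[i, 2] = fp1r / nrm
            out[i, 3] = fm1i / nrm
            out[i, 4] = fp1i / nrm
        else:
            m0 = np.abs(f0r)
            m1 = np.sqrt(fm1r * fm1r + fm1i * fm1i)
            m2 = np.sqrt(fp1r * fp1r + fp1i * fp1i)
            nrm = np.sqrt(m0 * m0 + m1 * m1 + m2 * m2)
            out[i, 0] = m1 / nrm
            out[i, 1] = m0 / nrm
            out[i, 2] = m2 / nrm


@njit(cache=True, fastmath=True)
def _noisy_features(sig_re, sig_im, eta, phi, complex_layout, out):
    """Feature pipeline from stored (noise-corrupted) complex signals."""
    n = sig_re.shape[0]
    npc = phi.shape[0]
    for i in range(n):
        mr = 0.0
        mi = 0.0
        for j in range(npc):
            mr += sig_re[i, j]
            mi += sig_im[i, j]
        mr /= npc
        mi /= npc
        mag = np.sqrt(mr * mr + mi * mi)
        if mag > 0.0:
            cr = mr / mag
            ci = -mi / mag
        else:
            cr = 1.0
            ci = 0.0
        fm1r = 0.0
        fm1i = 0.0
        f0r = 0.0
        f0i = 0.0
        fp1r = 0.0
        fp1i = 0.0
        for j in range(npc):
            vr = sig_re[i, j] * cr - sig_im[i, j] * ci
            vi = sig_re[i, j] * ci + sig_im[i, j] * cr
            cph = np.cos(phi[j])
            sph = np.sin(phi[j])
            fm1r += vr * cph - vi * sph
            fm1i += vi * cph + vr * sph
            f0r += vr
            f0i += vi
            fp1r += vr * cph + vi * sph
            fp1i += vi * cph - vr * sph
        fm1r /= npc
        fm1i /= npc
        f0r /= npc
        f0i /= npc
        fp1r /= npc
        fp1i /= npc
        if complex_layout:
            nrm = np.sqrt(
                fm1r * fm1r + f0r * f0r + fp1r * fp1r + fm1i * fm1i + fp1i * fp1i
            )
            out[i, 0] = fm1r / nrm
            out[i, 1] = f0r / nrm
            out[i, 2] = fp1r / nrm
            out[i, 3] = fm1i / nrm
            out[i, 4] = fp1i / nrm
        else:
            m0 = np.sqrt(f0r * f0r + f0i * f0i)
            m1 = np.sqrt(fm1r * fm1r + fm1i * fm1i)
            m2 = np.sqrt(fp1r * fp1r + fp1i * fp1i)
            nrm = np.sqrt(m0 * m0 + m1 * m1 + m2 * m2)
            out[i, 0] = m1 / nrm
            out[i, 1] = m0 / nrm
            out[i, 2] = m2 / nrm
    return out


@njit(cache=True, fastmath=True)
def svnn_epoch(
    X, Y, sig_re, sig_im, eta, phi, complex_layout,
    W1, b1, W2, b2, W3, b3, ms, vs, lr, bs, seed, tstep,
):
    """One supervised epoch.  If ``eta > 0`` features are recomputed per
    batch from freshly noise-corrupted signals; otherwise the precomputed
    clean features ``X`` are used.  Returns the updated Adam step count."""
    n = Y.shape[0]
    nb = n // bs
    np.random.seed(seed)
    perm = np.random.permutation(n)
    nf = X.shape[1] - 1
    ts = tstep
    for ib in range(nb):
        idx = perm[ib * bs:(ib + 1) * bs]
        Yb = Y[idx]
        if eta > 0.0:
            Xb = np.empty((bs, nf + 1), dtype=F32)
            nre = np.empty((bs, sig_re.shape[1]))
            nim = np.empty((bs, sig_re.shape[1]))
            for i in range(bs):
                for j in range(sig_re.shape[1]):
                    nre[i, j] = sig_re[idx[i], j] + eta * np.random.standard_normal()
                    nim[i, j] = sig_im[idx[i], j] + eta * np.random.standard_normal()
            feat = np.empty((bs, nf))
            _noisy_features(nre, nim, eta, phi, complex_layout, feat)
            for i in range(bs):
                for j in range(nf):
                    Xb[i, j] = feat[i, j]
                Xb[i, nf] = X[idx[i], nf]
        else:
            Xb = X[idx]
        a1, a2, s = _forward(Xb, W1, b1, W2, b2, W3, b3)
        d = (2.0 / (Yb.shape[0] * Yb.shape[1])) * (s - Yb) * s * (1.0 - s)
        d = d.astype(F32)
        ts += 1
        _backprop_update(Xb, a1, a2, s, d, W1, b1, W2, b2, W3, b3, ms, vs, lr, ts)
    return ts


@njit(cache=True, fastmath=True)
def _pinn_residual(s, b1v, xfeat, lo, hi, tr, te, alpha_rad, phi, complex_layout, out):
    """Per-sample physics residual: mean squared difference between the
    feature vector regenerated from the predicted parameters and the
    input feature vector (B1 entry excluded)."""
    n = s.shape[0]
    nf = xfeat.shape[1]
    nout = s.shape[1]
    t1 = np.empty(n)
    t2 = np.empty(n)
    th = np.empty(n)
    for i in range(n):
        t1[i] = lo[0] + s[i, 0] * (hi[0] - lo[0])
        t2[i] = lo[1] + s[i, 1] * (hi[1] - lo[1])
        th[i] = lo[2] + s[i, 2] * (hi[2] - lo[2]) if nout == 3 else 0.0
        if t1[i] < 1e-3:
            t1[i] = 1e-3
        if t2[i] < 1e-3:
            t2[i] = 1e-3
    feat = np.empty((n, nf))
    _features_batch(t1, t2, b1v, th, tr, te, alpha_rad, phi, complex_layout, feat)
    for i in range(n):
        acc = 0.0
        for j in range(nf):
            r = feat[i, j] - xfeat[i, j]
            acc += r * r
        out[i] = acc / nf


@njit(cache=True, fastmath=True)
def pinn_epoch(
    X, sig_re, sig_im, eta, phi, complex_layout, lo, hi, tr_, te_, alpha_rad,
    W1, b1, W2, b2, W3, b3, ms, vs, lr, bs, seed, tstep, fd_eps,
):
    """One physics-informed epoch (loss gradient by central differences)."""
    n = X.shape[0]
    nb = n // bs
    np.random.seed(seed)
    perm = np.random.permutation(n)
    nf = X.shape[1] - 1
    nout = 3 if complex_layout else 2
    ts = tstep
    lp = np.empty(bs)
    lm = np.empty(bs)
    for ib in range(nb):
        idx = perm[ib * bs:(ib + 1) * bs]
        if eta > 0.0:
            Xb = np.empty((bs, nf + 1), dtype=F32)
            nre = np.empty((bs, sig_re.shape[1]))
            nim = np.empty((bs, sig_re.shape[1]))
            for i in range(bs):
                for j in range(sig_re.shape[1]):
                    nre[i, j] = sig_re[idx[i], j] + eta * np.random.standard_normal()
                    nim[i, j] = sig_im[idx[i], j] + eta * np.random.standard_normal()
            feat = np.empty((bs, nf))
            _noisy_features(nre, nim, eta, phi, complex_layout, feat)
            for i in range(bs):
                for j in range(nf):
                    Xb[i, j] = feat[i, j]
                Xb[i, nf] = X[idx[i], nf]
        else:
            Xb = X[idx]
        a1, a2, s = _forward(Xb, W1, b1, W2, b2, W3, b3)
        s64 = s.astype(np.float64)
        xfeat = Xb[:, :nf].astype(np.float64)
        b1v = Xb[:, nf].astype(np.float64)
        d = np.empty((bs, nout), dtype=F32)
        for k in range(nout):
            sp = s64.copy()
            sm = s64.copy()
            for i in range(bs):
                sp[i, k] += fd_eps
                sm[i, k] -= fd_eps
            _pinn_residual(sp, b1v, xfeat, lo, hi, tr_, te_, alpha_rad, phi,
                           complex_layout, lp)
            _pinn_residual(sm, b1v, xfeat, lo, hi, tr_, te_, alpha_rad, phi,
                           complex_layout, lm)
            for i in range(bs):
                d[i, k] = F32((lp[i] - lm[i]) / (2.0 * fd_eps) / bs)
        d = (d * s * (1.0 - s)).astype(F32)
        ts += 1
        _backprop_update(Xb, a1, a2, s, d, W1, b1, W2, b2, W3, b3, ms, vs, lr, ts)
    return ts


def pinn_loss_values(s01, b1v, xfeat, lo, hi, seq, complex_layout):
    """Per-sample physics loss for validation (python-facing wrapper)."""
    out = np.empty(np.asarray(s01).shape[0])
    lo3 = np.zeros(3)
    hi3 = np.zeros(3)
    lo3[: len(lo)] = lo
    hi3[: len(hi)] = hi
    _pinn_residual(
        np.asarray(s01, dtype=np.float64),
        np.asarray(b1v, dtype=np.float64),
        np.asarray(xfeat, dtype=np.float64),
        lo3, hi3, float(seq.tr), float(seq.te), float(np.deg2rad(seq.alpha)),
        np.pi / seq.n_pc * (2 * np.arange(1, seq.n_pc + 1) - 1.0),
        complex_layout, out,
    )
    return out
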