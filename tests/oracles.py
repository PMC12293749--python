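"""Independent oracles shared between unit and acceptance tests.

These deliberately avoid the code paths they check: the k_PL oracle solves
the lactate ODE on a 100x refined time grid instead of the closed-form
inter-frame update used by the package.
"""

import numpy as np


def ode_oracle_kpl(pyr, lac, flip_deg=10.0, tr=4.2, t1_lac=25.0, refine=100):
    """Fine-grid ODE estimate of k_PL for one or many voxels.

    ``pyr``/``lac`` are (..., nt) measured amplitudes.  The lactate ODE
    dL/dt = kPL * P(t) - L/T1L is integrated at dt = TR/refine with P
    piecewise-linear between flip-corrected samples and cos(flip) losses at
    each excitation.  Because the ODE is linear in kPL, the least-squares
    estimate is closed-form: L_model = L0 * h(t) + kPL * q(t) with q from a
    single unit-kPL integration.
    """
    pyr = np.atleast_2d(np.asarray(pyr, dtype=float))
    lac = np.atleast_2d(np.asarray(lac, dtype=float))
    nvox, nt = pyr.shape
    a = np.deg2rad(flip_deg)
    cos_a = np.cos(a)
    e_step = np.exp(-(tr / refine) / t1_lac)
    dt = tr / refine

    # fit window starts at each voxel's pyruvate peak; handle per peak index
    out = np.full(nvox, np.nan)
    for i0 in np.unique(np.argmax(pyr, axis=1)):
        sel = np.argmax(pyr, axis=1) == i0
        p = pyr[sel][:, i0:]
        l = lac[sel][:, i0:]
        nwin = p.shape[1]
        if nwin < 5:
            continue
        # unit-kPL particular solution q at the frame times
        q = np.zeros((sel.sum(), nwin))
        qv = np.zeros(sel.sum())
        for n in range(nwin - 1):
            start, stop = p[:, n] * cos_a, p[:, n + 1]
            for s in range(refine):
                frac0 = s / refine
                frac1 = (s + 1) / refine
                p0 = start + (stop - start) * frac0
                p1 = start + (stop - start) * frac1
                # trapezoidal source over one fine step with exact decay
                qv = qv * e_step + 0.5 * dt * (p0 * e_step + p1)
            q[:, n + 1] = qv
            qv = qv * cos_a  # RF loss at the excitation
        decay = (cos_a * np.exp(-tr / t1_lac)) ** np.arange(nwin)
        resid = l - l[:, :1] * decay[None, :]
        num = (q[:, 1:] * resid[:, 1:]).sum(axis=1)
        den = (q[:, 1:] ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[sel] = np.clip(num / den, 0.0, None)
    return out if out.size > 1 else float(out[0])


def bky_reference(pvals, q=0.05):
    """Independently coded two-stage step-up discovery set (boolean vector).

    Literal transcription of the two-stage adaptive procedure: BH at
    q' = q/(1+q), estimate m0, BH again at q' * m/m0.  Written with explicit
    loops, no shared helpers with the package implementation.
    """
    p = list(pvals)
    m = len(p)
    qp = q / (1.0 + q)

    def bh(plist, level):
        order = sorted(range(len(plist)), key=lambda i: plist[i])
        kmax = -1
        for rank, idx in enumerate(order, start=1):
            if plist[idx] <= level * rank / len(plist):
                kmax = rank
        rejected = [False] * len(plist)
        for rank, idx in enumerate(order, start=1):
            if rank <= kmax:
                rejected[idx] = True
        return rejected

    stage1 = bh(p, qp)
    r1 = sum(stage1)
    if r1 == 0:
        return [False] * m
    if r1 == m:
        return [True] * m
    m0 = m - r1
    return bh(p, qp * m / m0)
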