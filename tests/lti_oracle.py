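"""Independent closed-form oracle for the model's linear regime.

When F01 = 0, St = Sd = 0 and Se = 0, with flat diurnal fluxes and no
meals, the whole 13-state system is linear time-invariant with constant
input: dy/dt = A y + b.  The exact solution is read off the matrix
exponential of the augmented system [[A, b], [0, 0]].  This module builds
A and b directly from the subsystem definitions — it never calls the
package's derivative or integration code.
"""
import numpy as np
from scipy.linalg import expm

IDX = {n: i for i, n in enumerate(
    ("Qis1", "Qis2", "Qif1", "Qif2", "Qi", "x1", "x2", "x3",
     "Qg1", "Qg2", "Q1", "Q2", "Gs"))}


def build_lti(p, ui: float, ug: float, im: float, fg: float):
    """System matrix A (13x13) and constant input vector b."""
    A = np.zeros((13, 13))
    b = np.zeros(13)
    c_ip = 1e6 / (p.Vi * p.w)               # Ip = c_ip * Qi
    c_cp = 1e6 / (p.tgmax * p.w * p.MCRg)   # Cp = c_cp * Qg2 + Cb

    A[0, 0] = -p.kis1
    b[0] = ui * p.pi
    A[1, 0] = p.kis1
    A[1, 1] = -p.kis2
    A[2, 2] = -p.kif
    b[2] = ui * (1 - p.pi)
    A[3, 2] = p.kif
    A[3, 3] = -p.kif
    A[4, 1] = p.kis2 * im
    A[4, 3] = p.kif * im
    A[4, 4] = -p.ke
    b[4] = p.ci
    for j, ka in ((5, p.ka1), (6, p.ka2), (7, p.ka3)):
        A[j, 4] = ka * c_ip
        A[j, j] = -ka
    A[8, 8] = -1.0 / p.tgmax
    b[8] = ug
    A[9, 8] = 1.0 / p.tgmax
    A[9, 9] = -1.0 / p.tgmax
    # dQ1 = k12 Q2 + Sg*(c_cp Qg2 + Cb) + fg   (F01 = St = Se = 0)
    A[10, 9] = p.Sg * c_cp
    A[10, 11] = p.k12
    b[10] = p.Sg * p.Cb + fg
    A[11, 11] = -p.k12
    A[12, 10] = p.ks / p.V
    A[12, 12] = -p.ks
    return A, b


def exact_solution(p, y0, t, ui=0.0, ug=0.0, im=1.0, fg=0.0):
    """State at time t from the augmented matrix exponential."""
    A, b = build_lti(p, ui, ug, im, fg)
    M = np.zeros((14, 14))
    M[:13, :13] = A
    M[:13, 13] = b
    z0 = np.append(np.asarray(y0, float), 1.0)
    return (expm(M * t) @ z0)[:13]
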