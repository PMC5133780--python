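"""Exchange–correlation functionals for the built-in Kohn–Sham engine.

Closed-shell forms of Slater exchange, Becke 88 gradient exchange, VWN
correlation (functional V and the RPA-fit functional III) and Lee–Yang–Parr
correlation. Energy densities are written symbolically once and their
derivatives with respect to rho and sigma = |grad rho|^2 are generated with
sympy, which removes the usual hand-derivation errors; the lambdified
callables operate on numpy arrays.

The hybrid used throughout is the three-parameter B3 mix
(a0, ax, ac) = (0.20, 0.72, 0.81): 20% exact exchange, 72% of the B88
gradient correction, 81% LYP against 19% VWN. The "vwn5" flavor uses VWN
functional V, the "vwn3" flavor the RPA fit (functional III).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

_B3 = {"a0": 0.20, "ax": 0.72, "ac": 0.81}

_RHO_FLOOR = 1e-12


def _vwn_eps(x, A, b, c, x0):
    X = x**2 + b * x + c
    X0 = x0**2 + b * x0 + c
    Q = sp.sqrt(4 * c - b**2)
    atn = sp.atan(Q / (2 * x + b))
    return A * (
        sp.log(x**2 / X) + 2 * b / Q * atn
        - b * x0 / X0 * (sp.log((x - x0) ** 2 / X) + 2 * (b + 2 * x0) / Q * atn)
    )


@lru_cache(maxsize=None)
def _build_callables():
    rho, sigma = sp.symbols("rho sigma", positive=True)

    # --- Slater exchange ---------------------------------------------------
    e_slater = -sp.Rational(3, 4) * (3 / sp.pi) ** sp.Rational(1, 3) * rho ** sp.Rational(4, 3)

    # --- B88 gradient correction (closed shell: rho_s = rho/2) -------------
    beta = sp.Float("0.0042")
    rho_s = rho / 2
    grad_s = sp.sqrt(sigma) / 2
    chi = grad_s / rho_s ** sp.Rational(4, 3)
    e_b88 = 2 * (-beta * rho_s ** sp.Rational(4, 3) * chi**2
                 / (1 + 6 * beta * chi * sp.asinh(chi)))

    # --- VWN correlation (paramagnetic, zeta = 0) ---------------------------
    rs = (3 / (4 * sp.pi * rho)) ** sp.Rational(1, 3)
    x = sp.sqrt(rs)
    A = sp.Float("0.0310907")
    e_vwn5 = rho * _vwn_eps(x, A, sp.Float("3.72744"), sp.Float("12.9352"),
                            sp.Float("-0.10498"))
    e_vwn3 = rho * _vwn_eps(x, A, sp.Float("13.0720"), sp.Float("42.7198"),
                            sp.Float("-0.409286"))

    # --- LYP correlation (closed shell) -------------------------------------
    a = sp.Float("0.04918")
    b = sp.Float("0.132")
    cpar = sp.Float("0.2533")
    d = sp.Float("0.349")
    CF = sp.Rational(3, 10) * (3 * sp.pi**2) ** sp.Rational(2, 3)
    ra = rho / 2
    rb = rho / 2
    saa = sigma / 4
    sbb = sigma / 4
    stot = sigma
    rm13 = rho ** sp.Rational(-1, 3)
    omega = sp.exp(-cpar * rm13) * rho ** sp.Rational(-11, 3) / (1 + d * rm13)
    delta = cpar * rm13 + d * rm13 / (1 + d * rm13)
    e_lyp = (
        -a * 4 / (1 + d * rm13) * ra * rb / rho
        - a * b * omega * (
            ra * rb * (
                2 ** sp.Rational(11, 3) * CF * (ra ** sp.Rational(8, 3) + rb ** sp.Rational(8, 3))
                + (sp.Rational(47, 18) - 7 * delta / 18) * stot
                - (sp.Rational(5, 2) - delta / 18) * (saa + sbb)
                - (delta - 11) / 9 * (ra / rho * saa + rb / rho * sbb)
            )
            - sp.Rational(2, 3) * rho**2 * stot
            + (sp.Rational(2, 3) * rho**2 - ra**2) * sbb
            + (sp.Rational(2, 3) * rho**2 - rb**2) * saa
        )
    )

    out = {}
    for name, expr in [("slater", e_slater), ("b88", e_b88),
                       ("vwn5", e_vwn5), ("vwn3", e_vwn3), ("lyp", e_lyp)]:
        f = sp.lambdify((rho, sigma), expr, modules="numpy")
        fr = sp.lambdify((rho, sigma), sp.diff(expr, rho), modules="numpy")
        fs = sp.lambdify((rho, sigma), sp.diff(expr, sigma), modules="numpy")
        out[name] = (f, fr, fs)
    return out


def eval_xc(rho: np.ndarray, sigma: np.ndarray, kind: str = "b3lyp5"):
    """Energy density e (per volume) and derivatives (de/drho, de/dsigma).

    kind: 'b3lyp5' (VWN functional V), 'b3lyp3' (VWN functional III RPA fit),
    or one of the components 'slater', 'b88', 'vwn5', 'vwn3', 'lyp'.
    The exact-exchange fraction (0.20 for the hybrids) is NOT included here.
    """
    funcs = _build_callables()
    rho = np.maximum(np.asarray(rho, float), _RHO_FLOOR)
    sigma = np.maximum(np.asarray(sigma, float), _RHO_FLOOR**2)

    if kind in funcs:
        mix = [(1.0, kind)]
    elif kind in ("b3lyp5", "b3lyp3"):
        vwn = "vwn5" if kind == "b3lyp5" else "vwn3"
        mix = [
            (1.0 - _B3["a0"], "slater"),
            (_B3["ax"], "b88"),
            (1.0 - _B3["ac"], vwn),
            (_B3["ac"], "lyp"),
        ]
    else:
        raise ValueError(f"unknown functional kind {kind!r}")

    e = np.zeros_like(rho)
    vr = np.zeros_like(rho)
    vs = np.zeros_like(rho)
    for w, name in mix:
        f, fr, fs = funcs[name]
        e += w * f(rho, sigma)
        vr += w * fr(rho, sigma)
        vs += w * fs(rho, sigma)
    return e, vr, vs


def exact_exchange_fraction(kind: str) -> float:
    return _B3["a0"] if kind in ("b3lyp5", "b3lyp3") else 0.0
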