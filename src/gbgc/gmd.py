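"""gBGC-mutation-drift (GMD) equilibrium model of genetic diversity.

At equilibrium between an S->W mutation bias lambda and a fixation bias of
strength B favoring strong alleles, GC content settles at

    x_GC = 1 / (1 + lambda * e^-B),

which reduces to the mutational equilibrium 1/(1+lambda) when B = 0.
Because gBGC raises equilibrium GC while the mutation bias keeps pushing
GC down, the two forces jointly increase the influx of new (mostly S->W)
mutations, and total diversity relative to the neutral B = 0 reference is

    pi_rel = [ 2 lam x_GC (1/(1-e^B) + 1/B)
             + 2 (1-x_GC) (1/(1-e^-B) - 1/B)
             + theta_N/theta_WS ]
             / [ 2 lam/(1+lam) + theta_N/theta_WS ],

with the three numerator terms giving the S->W, W->S and GC-conservative
contributions.  The model assumes full gBGC-mutation-drift equilibrium; it
makes no statement about transient GC trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GMDParams:
    """Parameter triple of the equilibrium model.

    ``theta_ratio`` is theta_N/theta_WS, the GC-conservative over W->S scaled
    diversity; 1 is the standard assumption when fits do not supply it.
    """

    B: float
    lam: float
    theta_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.theta_ratio <= 0:
            raise ValueError("theta_N/theta_WS must be positive")


def gc_equilibrium(lam, B):
    """Equilibrium GC content 1/(1 + lambda e^-B); 1/(1+lambda) at B=0."""
    lam = np.asarray(lam, dtype=float)
    if (lam <= 0).any():
        raise ValueError("lambda must be positive")
    out = 1.0 / (1.0 + lam * np.exp(-np.asarray(B, dtype=float)))
    return float(out) if out.ndim == 0 else out


def _h_plus(B):
    """1/(1-e^B) + 1/B with the B->0 limit 1/2 (S->W diversity factor)."""
    B = np.asarray(B, dtype=float)
    small = np.abs(B) < 1e-5
    Bs = np.where(small, 1.0, B)
    exact = 1.0 / -np.expm1(Bs) + 1.0 / Bs
    series = 0.5 - B / 12.0 + B ** 3 / 720.0
    return np.where(small, series, exact)


def _h_minus(B):
    """1/(1-e^-B) - 1/B with the B->0 limit 1/2 (W->S diversity factor)."""
    B = np.asarray(B, dtype=float)
    small = np.abs(B) < 1e-5
    Bs = np.where(small, 1.0, B)
    exact = 1.0 / -np.expm1(-Bs) - 1.0 / Bs
    series = 0.5 + B / 12.0 - B ** 3 / 720.0
    return np.where(small, series, exact)


def _denominator(lam, theta_ratio):
    return 2.0 * lam / (1.0 + lam) + theta_ratio


def pi_rel(params: GMDParams) -> float:
    """Equilibrium diversity relative to the neutral (B = 0) reference.

    Exactly 1 at B = 0 for any lambda and theta ratio; continuous there via
    a series expansion of both bracketed factors.
    """
    lam, B, t = params.lam, params.B, params.theta_ratio
    x = gc_equilibrium(lam, B)
    num = 2.0 * lam * x * _h_plus(B) + 2.0 * (1.0 - x) * _h_minus(B) + t
    return float(num / _denominator(lam, t))


def pi_rel_decomposed(params: GMDParams,
                      theta_ss_ratio: float | None = None,
                      theta_ww_ratio: float | None = None) -> dict[str, float]:
    """Per-category relative diversities, standardized by mutational opportunity.

    Components satisfy the exact reconstruction
    x_GC*SW + (1-x_GC)*WS + x_GC*SS + (1-x_GC)*WW = pi_rel
    when theta_SS/theta_WS = theta_WW/theta_WS = theta_N/theta_WS (the
    default split of the GC-conservative diversity).
    """
    lam, B, t = params.lam, params.B, params.theta_ratio
    t_ss = t if theta_ss_ratio is None else theta_ss_ratio
    t_ww = t if theta_ww_ratio is None else theta_ww_ratio
    D = _denominator(lam, t)
    return {
        "SW": float(2.0 * lam * _h_plus(B) / D),
        "WS": float(2.0 * _h_minus(B) / D),
        "SS": float(t_ss / D),
        "WW": float(t_ww / D),
        "x_GC": gc_equilibrium(lam, B),
    }


def predict_boost(centile_fits) -> float:
    """Mean percent change in equilibrium pi vs the B = 0 reference.

    ``centile_fits`` is an iterable of GMDParams (or (lam, B) /
    (lam, B, theta_ratio) tuples, note the argument order of GMDParams is
    (B, lam, ...)); returns mean over entries of 100*(pi_rel - 1).
    """
    vals = []
    for entry in centile_fits:
        if not isinstance(entry, GMDParams):
            lam, B, *rest = entry
            entry = GMDParams(B=B, lam=lam, theta_ratio=rest[0] if rest else 1.0)
        vals.append(pi_rel(entry) - 1.0)
    if not vals:
        raise ValueError("no fits supplied")
    return float(100.0 * np.mean(vals))


def robustness_sample(params: GMDParams, sd_lam: float, sd_B: float,
                      n_draws: int, seed: int) -> dict:
    """Propagate estimation error in (lambda, B) through the GMD model.

    Draws both parameters from normal distributions centered on the point
    values (draws with lambda <= 0 are rejected and redrawn), evaluates the
    decomposed model for each draw, and returns the draws with 2.5/50/97.5
    percentile envelopes per component.
    """
    if sd_lam < 0 or sd_B < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        lam = rng.normal(params.lam, sd_lam)
        while lam <= 0:
            lam = rng.normal(params.lam, sd_lam)
        B = rng.normal(params.B, sd_B)
        p = GMDParams(B=B, lam=lam, theta_ratio=params.theta_ratio)
        comp = pi_rel_decomposed(p)
        comp.update({"lambda": lam, "B": B, "pi_rel": pi_rel(p)})
        draws.append(comp)
    keys = ("SW", "WS", "SS", "WW", "pi_rel", "x_GC")
    env = {}
    for k in keys:
        v = np.array([d[k] for d in draws])
        env[k] = {"q2.5": float(np.percentile(v, 2.5)),
                  "median": float(np.percentile(v, 50)),
                  "q97.5": float(np.percentile(v, 97.5))}
    return {"draws": draws, "envelope": env}
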