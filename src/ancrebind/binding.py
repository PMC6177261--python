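"""Equilibrium and kinetic binding-model fits.

Equilibrium: the quadratic (ligand-depletion) isotherm for a 1:1 complex of
protein P with labeled DNA at fixed total concentration D,

    F = b0 + (bM - b0) * [D + P + 1/KA - sqrt((D + P + 1/KA)^2 - 4 P D)] / (2 D),

which reduces to the hyperbolic Langmuir form as D -> 0. KA is fit on a
log10 scale to keep it positive and well conditioned.

Kinetics: the 1:1 SPR association-phase model

    R(t) = kon c0 Rmax / (kon c0 + koff) * [1 - exp(-(kon c0 + koff) t)]
           + R_RI + cD t,

with refractive-index offset R_RI and baseline drift cD; the dissociation
phase is a single exponential with optional drift. Derived quantities:
KD = koff/kon and residence time tau = 1/koff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

# ---------------------------------------------------------------------------
# containers


@dataclass
class TitrationSeries:
    """F-EMSA titration: bound fraction F vs total protein concentration P
    at fixed labeled-DNA concentration D (all concentrations molar)."""

    D: float
    P: np.ndarray
    F: np.ndarray
    motif: str = ""
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.D <= 0:
            raise ValueError("DNA concentration D must be > 0")
        if np.any(self.P < 0):
            raise ValueError("protein concentrations must be >= 0")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("bound fractions must be finite")
        if self.replicate is None:
            order = np.argsort(self.P, kind="stable")
            if np.any(np.diff(self.P[order]) < 0):  # defensive; sorted below
                raise ValueError("unsortable P grid")
            self.P, self.F = self.P[order], self.F[order]

    def split_replicates(self) -> list["TitrationSeries"]:
        if self.replicate is None:
            return [self]
        out = []
        for rep in np.unique(self.replicate):
            m = self.replicate == rep
            out.append(TitrationSeries(D=self.D, P=self.P[m], F=self.F[m],
                                       motif=self.motif))
        return out


@dataclass
class Sensorgram:
    """SPR time series at one analyte concentration."""

    t: np.ndarray
    R: np.ndarray
    c0: float
    phase: str = "association"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.phase == "association":
            if self.c0 <= 0:
                raise ValueError("analyte concentration must be > 0")
            if self.t[0] < 0:
                raise ValueError("association phase starts at t >= 0")


@dataclass
class QuadraticBindingFit:
    """Quadratic-isotherm fit: baseline b0, maximum bM, association KA."""

    b0: float
    bM: float
    KA: float
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    n: int = 0
    warnings_: list[str] = field(default_factory=list)

    @property
    def Kd(self) -> float:
        return 1.0 / self.KA

    def ci95_KA(self) -> tuple[float, float]:
        """95% interval for KA from the SE of log10 KA."""
        s = self.se.get("log10_KA")
        if s is None or not np.isfinite(s):
            return (float("nan"), float("nan"))
        lg = np.log10(self.KA)
        return (10 ** (lg - 1.96 * s), 10 ** (lg + 1.96 * s))

    def to_dict(self) -> dict:
        return {"b0": self.b0, "bM": self.bM, "KA": self.KA, "Kd": self.Kd,
                "se": self.se, "rss": self.rss, "n": self.n,
                "warnings": self.warnings_}


@dataclass
class KineticFit:
    """1:1 SPR kinetic fit with refractive-index and drift corrections."""

    kon: float
    koff: float
    Rmax: float
    R_RI: float | np.ndarray
    cD: float
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    n: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def KD(self) -> float:
        return self.koff / self.kon

    @property
    def residence_time(self) -> float:
        return 1.0 / self.koff

    def to_dict(self) -> dict:
        ri = self.R_RI
        return {"kon": self.kon, "koff": self.koff, "Rmax": self.Rmax,
                "R_RI": ri.tolist() if isinstance(ri, np.ndarray) else ri,
                "cD": self.cD, "KD": self.KD,
                "residence_time": self.residence_time,
                "se": self.se, "rss": self.rss, "n": self.n,
                "flags": self.flags}


# ---------------------------------------------------------------------------
# equilibrium


def eval_isotherm(b0: float, bM: float, KA: float, D: float,
                  P: np.ndarray) -> np.ndarray:
    """Quadratic bound-fraction isotherm; discriminant floored at 0."""
    P = np.asarray(P, dtype=float)
    term = D + P + 1.0 / KA
    disc = term * term - 4.0 * P * D
    root = np.sqrt(np.maximum(disc, 0.0))
    return b0 + (bM - b0) * (term - root) / (2.0 * D)


def _isotherm_init(data: TitrationSeries) -> tuple[float, float, float]:
    b0 = float(np.min(data.F))
    bM = float(np.max(data.F))
    half = 0.5 * (b0 + bM)
    # P at half-maximal signal approximates Kd + D/2
    idx = np.argsort(data.F)
    P_half = float(np.interp(half, data.F[idx], data.P[idx]))
    Kd0 = max(P_half - data.D / 2.0, data.D / 100.0)
    return b0, bM, 1.0 / Kd0


def fit_quadratic_isotherm(data: TitrationSeries,
                           init: tuple[float, float, float] | None = None
                           ) -> QuadraticBindingFit:
    """Nonlinear least-squares fit of (b0, bM, KA) to a titration series.

    KA is parameterized as log10 KA. Standard errors come from the Jacobian
    at the optimum; a warning is recorded when the titration does not span
    the binding transition.
    """
    if data.P.size < 5:
        raise ValueError("need at least 5 titration points")
    b0_0, bM_0, KA_0 = init if init is not None else _isotherm_init(data)
    warn: list[str] = []

    def resid(theta):
        b0, bM, lgKA = theta
        lgKA = np.clip(lgKA, -6.0, 20.0)
        return eval_isotherm(b0, bM, 10.0 ** lgKA, data.D, data.P) - data.F

    x0 = np.array([b0_0, bM_0, np.log10(KA_0)])
    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    b0, bM, lgKA = sol.x
    lgKA = float(np.clip(lgKA, -6.0, 20.0))
    KA = 10.0 ** lgKA
    span = bM - b0
    if span != 0:
        frac = (data.F - b0) / span
        if np.all(frac < 0.05) or np.all(frac > 0.95):
            warn.append("poorly constrained KA: titration does not span "
                        "the binding transition")
    rss = float((sol.fun ** 2).sum())
    dof = max(data.P.size - 3, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.diag(cov))
        se_d = {"b0": float(se[0]), "bM": float(se[1]),
                "log10_KA": float(se[2]),
                "KA": float(se[2] * np.log(10) * KA)}
    except np.linalg.LinAlgError:
        se_d = {}
        warn.append("singular Jacobian; no standard errors")
    for w in warn:
        warnings.warn(w)
    return QuadraticBindingFit(b0=float(b0), bM=float(bM), KA=float(KA),
                               se=se_d, rss=rss, n=int(data.P.size),
                               warnings_=warn)


def fit_titration_replicates(data: TitrationSeries) -> dict:
    """Fit each replicate independently; report per-replicate KA and
    mean +/- SEM, the presentation used for triplicate EMSA series."""
    series = data.split_replicates()
    fits = [fit_quadratic_isotherm(s) for s in series]
    kas = np.array([f.KA for f in fits])
    sem = float(kas.std(ddof=1) / np.sqrt(len(kas))) if len(kas) > 1 else 0.0
    return {"fits": fits, "KA_mean": float(kas.mean()), "KA_sem": sem,
            "Kd_mean": float((1 / kas).mean()),
            "Kd_sem": float((1 / kas).std(ddof=1) / np.sqrt(len(kas)))
            if len(kas) > 1 else 0.0}


# ---------------------------------------------------------------------------
# kinetics


def eval_association(t: np.ndarray, kon: float, koff: float, Rmax: float,
                     c0: float, R_RI: float = 0.0, cD: float = 0.0
                     ) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    kobs = kon * c0 + koff
    plateau = kon * c0 * Rmax / kobs
    return plateau * (1.0 - np.exp(-kobs * t)) + R_RI + cD * t


def _single_curve_kobs(gram: Sensorgram) -> tuple[float, float]:
    """Fit A(1-exp(-kobs t)) + c to one association curve; returns (kobs, A)."""
    t, R = gram.t, gram.R
    A0 = float(R.max() - R.min())
    span = t[-1] - t[0]

    def resid(theta):
        A, kobs, c = theta
        return A * (1 - np.exp(-kobs * t)) + c - R

    sol = least_squares(resid, [max(A0, 1e-6), 2.0 / max(span, 1e-9), R[0]],
                        bounds=([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                        max_nfev=2000)
    return float(sol.x[1]), float(sol.x[0])


def kobs_linearization(grams: list[Sensorgram]) -> dict:
    """Two-stage estimate: per-curve kobs, then linear fit kobs = kon c0 + koff."""
    if len(grams) < 2:
        raise ValueError("need >= 2 concentrations for kobs linearization")
    c0s = np.array([g.c0 for g in grams])
    kobs = np.array([_single_curve_kobs(g)[0] for g in grams])
    slope, intercept = np.polyfit(c0s, kobs, 1)
    return {"kon": float(slope), "koff": float(intercept),
            "kobs": kobs, "c0": c0s}


def fit_association(grams: Sensorgram | list[Sensorgram],
                    init: dict | None = None,
                    shared_drift: bool = True) -> KineticFit:
    """Fit the association-phase model; global over a list of sensorgrams.

    The global fit shares kon, koff and Rmax across concentrations with a
    per-curve refractive-index offset R_RI; drift cD is shared by default.
    Rate constants are parameterized on a log10 scale.
    """
    single = isinstance(grams, Sensorgram)
    glist = [grams] if single else list(grams)
    if not glist:
        raise ValueError("no sensorgrams supplied")
    for g in glist:
        if g.phase != "association":
            raise ValueError("fit_association requires association-phase data")
    if init is None:
        if len(glist) >= 2:
            lin = kobs_linearization(glist)
            kon0 = max(lin["kon"], 1e2)
            koff0 = max(lin["koff"], 1e-5)
        else:
            kobs, _ = _single_curve_kobs(glist[0])
            koff0 = kobs / 2
            kon0 = kobs / 2 / glist[0].c0
        Rmax0 = max(max(g.R.max() - g.R.min() for g in glist), 1e-3)
    else:
        kon0, koff0, Rmax0 = init["kon"], init["koff"], init["Rmax"]
    nc = len(glist)

    def unpack(theta):
        kon, koff = 10.0 ** theta[0], 10.0 ** theta[1]
        Rmax = theta[2]
        cD = theta[3]
        R_RI = theta[4:4 + nc]
        return kon, koff, Rmax, cD, R_RI

    def resid(theta):
        kon, koff, Rmax, cD, R_RI = unpack(theta)
        parts = [eval_association(g.t, kon, koff, Rmax, g.c0, R_RI[i], cD) - g.R
                 for i, g in enumerate(glist)]
        return np.concatenate(parts)

    x0 = np.concatenate([[np.log10(kon0), np.log10(koff0), Rmax0, 0.0],
                         [float(g.R[0]) for g in glist]])
    sol = least_squares(resid, x0, method="lm", max_nfev=5000)
    kon, koff, Rmax, cD, R_RI = unpack(sol.x)
    flags = []
    if np.log10(koff) < -6:
        flags.append("koff at lower bound; dissociation unresolved")
    rss = float((sol.fun ** 2).sum())
    n = sum(g.t.size for g in glist)
    dof = max(n - sol.x.size, 1)
    try:
        cov = rss / dof * np.linalg.inv(sol.jac.T @ sol.jac)
        dg = np.sqrt(np.diag(cov))
        se = {"log10_kon": float(dg[0]), "log10_koff": float(dg[1]),
              "Rmax": float(dg[2]), "cD": float(dg[3]),
              "kon": float(dg[0] * np.log(10) * kon),
              "koff": float(dg[1] * np.log(10) * koff)}
    except np.linalg.LinAlgError:
        se = {}
    return KineticFit(kon=float(kon), koff=float(koff), Rmax=float(Rmax),
                      R_RI=float(R_RI[0]) if single else np.asarray(R_RI),
                      cD=float(cD), se=se, rss=rss, n=n, flags=flags)


def eval_dissociation(t: np.ndarray, R1: float, koff: float, t1: float,
                      baseline: float = 0.0, drift: float = 0.0) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return R1 * np.exp(-koff * (t - t1)) + baseline + drift * (t - t1)


def fit_dissociation(gram: Sensorgram, with_drift: bool = False) -> KineticFit:
    """Fit a single-exponential decay (optional linear drift) to the
    dissociation phase; raises on a non-decaying signal."""
    t, R = gram.t, gram.R
    t1 = t[0]
    if np.ptp(R) == 0 or R[-1] >= R[0]:
        raise ValueError("dissociation signal does not decay")
    A0 = float(R[0] - R[-1])
    span = t[-1] - t1

    def resid(theta):
        R1, lgkoff, base = theta[0], theta[1], theta[2]
        drift = theta[3] if with_drift else 0.0
        return eval_dissociation(t, R1, 10.0 ** lgkoff, t1, base, drift) - R

    x0 = [A0, np.log10(2.0 / span), float(R[-1])]
    if with_drift:
        x0 = x0 + [0.0]
    sol = least_squares(resid, x0, method="lm", max_nfev=5000)
    koff = 10.0 ** sol.x[1]
    if sol.x[0] <= 0:
        raise ValueError("dissociation fit found non-positive amplitude")
    rss = float((sol.fun ** 2).sum())
    return KineticFit(kon=float("nan"), koff=float(koff), Rmax=float(sol.x[0]),
                      R_RI=float(sol.x[2]),
                      cD=float(sol.x[3]) if with_drift else 0.0,
                      rss=rss, n=t.size)


def residence_time(fit: KineticFit) -> float:
    """Mean complex lifetime tau = 1/koff (seconds)."""
    if not fit.koff > 0:
        raise ValueError("koff must be > 0")
    return 1.0 / fit.koff


# ---------------------------------------------------------------------------
# comparative quantities


@dataclass
class PreferenceComparison:
    """Per-protein BM/ZM preference and its evolutionary shift."""

    preference_a: float
    preference_b: float
    shift: float
    kind: str
    residence_ratio_bm: float | None = None
    residence_ratio_zm: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _affinity(fit) -> tuple[float, str]:
    if isinstance(fit, QuadraticBindingFit):
        return fit.KA, "equilibrium"
    if isinstance(fit, KineticFit):
        return 1.0 / fit.KD, "kinetic"
    raise TypeError(f"unsupported fit type {type(fit).__name__}")


def compare_preference(fit_a_bm, fit_a_zm, fit_b_bm, fit_b_zm,
                       allow_mixed: bool = False) -> PreferenceComparison:
    """Preference = KA(BM)/KA(ZM) per protein; shift = preference(B)/preference(A).

    Kinetic fits contribute 1/KD as the affinity; mixing equilibrium and
    kinetic affinities requires ``allow_mixed=True``.
    """
    vals, kinds = zip(*(_affinity(f) for f in
                        (fit_a_bm, fit_a_zm, fit_b_bm, fit_b_zm)))
    if len(set(kinds)) > 1 and not allow_mixed:
        raise ValueError("mixing equilibrium and kinetic affinities; "
                         "pass allow_mixed=True if intended")
    pref_a = vals[0] / vals[1]
    pref_b = vals[2] / vals[3]
    out = PreferenceComparison(preference_a=pref_a, preference_b=pref_b,
                               shift=pref_b / pref_a, kind=kinds[0])
    if all(isinstance(f, KineticFit) for f in
           (fit_a_bm, fit_a_zm, fit_b_bm, fit_b_zm)):
        out.residence_ratio_bm = fit_a_bm.koff / fit_b_bm.koff
        out.residence_ratio_zm = fit_a_zm.koff / fit_b_zm.koff
    return out


def write_fit_report(path, fits: dict) -> None:
    """Serialize a dictionary of fit objects to JSON."""
    def enc(v):
        if hasattr(v, "to_dict"):
            return v.to_dict()
        return v
    with open(path, "w") as fh:
        json.dump({k: enc(v) for k, v in fits.items()}, fh, indent=1)
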