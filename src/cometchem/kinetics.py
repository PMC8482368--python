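"""Label-incorporation kinetics: half-lives, turnover, and reaction rates.

The measured quantity per acetylation site is the heavy-to-total fraction
f(t) = H/(H+L) of the endogenous acetyl label after the switch of the glucose
(and hence acetyl-CoA) pool to the 13C form. Under first-order site kinetics
f grows as

    f(t) = p * (1 - exp(-k t)),

where the plateau p equals the heavy fraction of the acetyl-CoA pool and k is
the site's deacetylation (label-exchange) rate; the half-life is t1/2 = ln2/k.
For the fully acetylated species a single-parameter decay r(t) = 100*exp(-kt)
is fitted to the fraction of the pre-existing (all-light) species among all
fully acetylated species, whose intercept is exactly 100% at t = 0.

Reaction rates come from the initial-flux linearization: the early-time slope
of a product species divided by the substrate abundance at t = 0 estimates a
first-order rate. Because post-switch acetylation still deposits *light*
acetyl with probability 1 - p, every such raw estimate scales with the
acetyl-CoA plateau; the model therefore divides by the plateau estimated from
the growth fits (set ``label_plateau=1`` to reproduce the raw definition).

`AcetylationKineticsModel` wraps a tidy per-state abundance table and `fit()`
returns an `AcetylationKineticsResults` carrying fits, turnovers, rate
estimates and a `summary()` table.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .mass_model import PeptideSpec

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "TurnoverResult",
    "FluxResult",
    "RateEstimate",
    "Reaction",
    "ReactionNetwork",
    "state_strings",
    "label_fraction",
    "fit_growth",
    "fit_decay_fixed_intercept",
    "turnover",
    "build_network",
    "initial_flux",
    "reaction_rate",
    "AcetylationKineticsModel",
    "AcetylationKineticsResults",
]

LN2 = math.log(2.0)

#: Per-site in vivo states: unmodified, light acetyl, heavy acetyl.
STATE_CHARS = ("U", "L", "H")


def state_strings(n_sites: int) -> list[str]:
    """All 3**n in vivo species as strings over U/L/H, site order preserved."""
    return ["".join(c) for c in itertools.product(STATE_CHARS, repeat=n_sites)]


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Exponential fit of a label time course.

    ``p`` is the plateau (pre-factor, same scale as the input series), ``k``
    the exponential rate in 1/h, with standard deviations from the fit
    covariance; ``t_half_min`` = ln2/k in minutes.
    """

    model: str
    p: float
    k: float
    sigma_p: float
    sigma_k: float
    ok: bool
    message: str = ""
    residuals: tuple[float, ...] = ()

    @property
    def t_half_min(self) -> float:
        return LN2 / self.k * 60.0 if self.k > 1e-9 else float("inf")


def label_fraction(heavy: np.ndarray, light: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """f = H/(H+L) with undefined points (H+L = 0) masked out.

    Returns (mask, f) where ``mask`` marks the defined points. Raises if all
    points are undefined.
    """
    heavy = np.asarray(heavy, dtype=float)
    light = np.asarray(light, dtype=float)
    total = heavy + light
    mask = total > 0
    if not mask.any():
        raise ValueError("label fraction undefined at every point (H+L = 0)")
    if not mask.all():
        logger.info("dropping %d undefined label-fraction points", int((~mask).sum()))
    f = np.full_like(total, np.nan)
    f[mask] = heavy[mask] / total[mask]
    return mask, f


def fit_growth(t_min: np.ndarray, f: np.ndarray) -> FitResult:
    """Fit f(t) = p (1 - exp(-k t)) to a heavy-fraction time course.

    ``t_min`` in minutes; ``k`` is reported in 1/h. Requires >= 4 distinct
    time points; a non-converged or non-positive-rate fit is returned with
    ``ok=False`` rather than raised.
    """
    t = np.asarray(t_min, dtype=float) / 60.0
    f = np.asarray(f, dtype=float)
    keep = np.isfinite(f)
    t, f = t[keep], f[keep]
    if len(np.unique(t)) < 4:
        raise ValueError("growth fit needs >= 4 distinct time points")
    if np.any((f < -1e-9) | (f > 1.0 + 1e-9)):
        raise ValueError("heavy fractions must lie in [0, 1]")

    def model(tt, p, k):
        return p * (1.0 - np.exp(-k * tt))

    try:
        popt, pcov = curve_fit(
            model, t, f, p0=(max(f.max(), 0.1), 0.1),
            bounds=((0.0, 1e-9), (1.5, 1e3)), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger deterministically
        return FitResult("growth", math.nan, math.nan, math.nan, math.nan, False, str(exc))
    p_hat, k_hat = popt
    sig = np.sqrt(np.diag(pcov))
    resid = f - model(t, *popt)
    ok = bool(k_hat > 0 and np.isfinite(sig).all())
    return FitResult(
        "growth", float(p_hat), float(k_hat), float(sig[0]), float(sig[1]),
        ok, "" if ok else "rate not identifiable", tuple(resid.tolist()),
    )


def fit_growth_fixed_plateau(t_min: np.ndarray, f: np.ndarray, plateau: float) -> FitResult:
    """Fit f(t) = p0 (1 - exp(-k t)) with the plateau pinned.

    Used for the shared-plateau refinement: all sites draw on the same
    acetyl-CoA pool, so their label-exchange curves share one plateau. With p
    fixed the rate is well determined even when a slow site's curve is far
    from saturation (where the free (p, k) fit is ridge-degenerate).
    """
    t = np.asarray(t_min, dtype=float) / 60.0
    f = np.asarray(f, dtype=float)
    keep = np.isfinite(f)
    t, f = t[keep], f[keep]
    if len(np.unique(t)) < 3:
        raise ValueError("fixed-plateau growth fit needs >= 3 distinct time points")
    if not 0 < plateau <= 1.0:
        raise ValueError("plateau must be in (0, 1]")

    def model(tt, k):
        return plateau * (1.0 - np.exp(-k * tt))

    popt, pcov = curve_fit(model, t, f, p0=(0.1,), bounds=((1e-9,), (1e3,)), maxfev=20000)
    k_hat = float(popt[0])
    sig_k = float(np.sqrt(pcov[0, 0]))
    resid = f - model(t, k_hat)
    ok = bool(k_hat > 0 and np.isfinite(sig_k))
    return FitResult(
        "growth-fixed-plateau", plateau, k_hat, 0.0, sig_k,
        ok, "" if ok else "rate not identifiable", tuple(resid.tolist()),
    )


def fit_decay_fixed_intercept(t_min: np.ndarray, r_pct: np.ndarray) -> FitResult:
    """Fit r(t) = 100 exp(-k t) with the intercept pinned at 100%.

    Used for the pre-existing (all-light) fully acetylated species as a
    fraction of all fully acetylated species, which is exactly 100% at t = 0.
    A flat or increasing series yields ``ok=False`` (no decay, t1/2 -> inf).
    """
    t = np.asarray(t_min, dtype=float) / 60.0
    r = np.asarray(r_pct, dtype=float)
    keep = np.isfinite(r)
    t, r = t[keep], r[keep]
    if len(np.unique(t)) < 3:
        raise ValueError("decay fit needs >= 3 distinct time points")
    if abs(r[np.argmin(t)] - 100.0) > 20.0:
        logger.warning("decay series starts at %.1f%%, far from the fixed 100%% intercept", r[np.argmin(t)])

    def model(tt, k):
        return 100.0 * np.exp(-k * tt)

    popt, pcov = curve_fit(model, t, r, p0=(0.1,), bounds=((1e-12,), (1e3,)), maxfev=20000)
    k_hat = float(popt[0])
    sig_k = float(np.sqrt(pcov[0, 0]))
    resid = r - model(t, k_hat)
    # decay of less than ~1e-4 % over the whole observation span is noise
    if k_hat * float(t.max()) < 1e-6:
        return FitResult(
            "decay-fixed-intercept", 100.0, 0.0, 0.0, sig_k,
            False, "no measurable decay", tuple(resid.tolist()),
        )
    ok = np.isfinite(sig_k)
    return FitResult(
        "decay-fixed-intercept", 100.0, k_hat, 0.0, sig_k,
        bool(ok), "" if ok else "no measurable decay", tuple(resid.tolist()),
    )


# ---------------------------------------------------------------------------
# turnover
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TurnoverResult:
    """Abundance-corrected turnover k*A of one species."""

    species: str
    k_per_h: float
    abundance_pct: float
    turnover_pct_per_h: float


def turnover(fit: FitResult | float, abundance_pct: float, species: str = "") -> TurnoverResult:
    """Abundance-corrected turnover k*A (%/h) from a fit or a bare rate (1/h)."""
    if isinstance(fit, FitResult):
        if not fit.ok:
            raise ValueError("turnover requires an accepted fit")
        k = fit.k
    else:
        k = float(fit)
    if abundance_pct < 0:
        raise ValueError("abundance must be >= 0")
    return TurnoverResult(species, k, abundance_pct, k * abundance_pct)


# ---------------------------------------------------------------------------
# reaction network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One acetylation or deacetylation edge between in vivo species."""

    kind: str        # "acetylation" | "deacetylation"
    site: int        # 0-based site position
    substrate: str   # state string
    product: str
    estimable: bool  # initial-flux fitting possible (substrate heavy-free)
    label: str = ""


@dataclass(frozen=True)
class ReactionNetwork:
    """Species nodes and typed edges of the per-site label network."""

    n_sites: int
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def estimable(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.estimable)


def _conventional_reaction_label(kind: str, site: int, substrate: str) -> str:
    """Conventional a1..a4 / d1..d3 labels for the two-site peptide."""
    n = len(substrate)
    ctx = frozenset(i for i, c in enumerate(substrate) if c != "U" and i != site)
    if n == 2:
        if kind == "acetylation":
            if not ctx:
                return "a1" if site == 0 else "a2"
            return "a4" if site == 0 else "a3"
        if substrate.count("U") == n - 1:
            return "d1" if site == 0 else "d2"
        if substrate == "LL" or substrate == "L" * n:
            return "d3"
    ctx_tag = "".join(str(i) for i in sorted(ctx)) or "-"
    return f"{kind[0]}[s{site}|ctx{ctx_tag}]"


def build_network(n_sites: int) -> ReactionNetwork:
    """Enumerate the 3**n species and their interconversion reactions.

    Acetylation edges point from an unmodified site to the heavy state (the
    post-switch substrate pool); deacetylation edges leave both the light and
    the heavy state. Edges whose substrate contains a heavy label are marked
    non-estimable: those substrates are absent at t = 0, so initial-flux
    fitting is impossible for them.
    """
    if not 1 <= n_sites <= 6:
        raise ValueError("n_sites must be in 1..6")
    species = state_strings(n_sites)
    reactions = []
    for s in species:
        heavy_free = "H" not in s
        for i, c in enumerate(s):
            if c == "U":
                prod = s[:i] + "H" + s[i + 1:]
                reactions.append(
                    Reaction("acetylation", i, s, prod, heavy_free,
                             _conventional_reaction_label("acetylation", i, s))
                )
            else:
                prod = s[:i] + "U" + s[i + 1:]
                reactions.append(
                    Reaction("deacetylation", i, s, prod, heavy_free,
                             _conventional_reaction_label("deacetylation", i, s))
                )
    return ReactionNetwork(n_sites, tuple(species), tuple(reactions))


# ---------------------------------------------------------------------------
# initial fluxes and rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxResult:
    """OLS slope of an early-time abundance window."""

    slope_pct_per_h: float
    stderr: float
    intercept_pct: float
    intercept_stderr: float
    n_points: int


def initial_flux(
    t_min: np.ndarray,
    y_pct: np.ndarray,
    window_h: float = 4.0,
    max_points: int = 4,
    intercept_at: float | None = None,
) -> FluxResult:
    """Least-squares slope over the initial window.

    The window keeps the first ``max_points`` time points restricted to
    t <= ``window_h`` (whichever gives fewer points); at least 3 points are
    required. When the t = 0 value is known exactly (a heavy-labeled product
    species is absent before the label switch; a light-retention ratio starts
    at 100%), pass it as ``intercept_at`` to fit the slope through that fixed
    intercept — the noisy measured t = 0 point then carries zero weight.
    """
    t = np.asarray(t_min, dtype=float) / 60.0
    y = np.asarray(y_pct, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    inside = t <= window_h + 1e-12
    idx = np.where(inside)[0][:max_points]
    if len(idx) < 3:
        raise ValueError(
            f"initial-flux window holds {len(idx)} points; >= 3 required"
        )
    tw, yw = t[idx], y[idx]
    if intercept_at is None:
        res = linregress(tw, yw)
        return FluxResult(
            float(res.slope), float(res.stderr), float(res.intercept),
            float(res.intercept_stderr), int(len(idx)),
        )
    dz = yw - intercept_at
    stt = float(np.sum(tw * tw))
    if stt <= 0:
        raise ValueError("initial-flux window has no positive time points")
    slope = float(np.sum(tw * dz) / stt)
    resid = dz - slope * tw
    dof = max(len(tw) - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / stt))
    return FluxResult(slope, se, float(intercept_at), 0.0, int(len(idx)))


@dataclass(frozen=True)
class RateEstimate:
    """First-order rate from an initial flux and a substrate abundance."""

    reaction: str
    kind: str
    site_name: str
    slope_pct_per_h: float
    slope_stderr: float
    substrate_a0_pct: float
    rate_per_h: float
    rate_stderr: float
    estimable: bool
    replicate: object = None


def reaction_rate(
    slope_pct_per_h: float,
    substrate_a0_pct: float,
    label_plateau: float = 1.0,
    slope_stderr: float = 0.0,
    reaction: str = "",
    kind: str = "",
    site_name: str = "",
    replicate: object = None,
) -> RateEstimate:
    """Convert an initial flux into a first-order rate v = slope / (A0 * p).

    ``label_plateau`` is the heavy fraction of the acetyl-CoA pool (the growth
    fits' plateau p); at 1.0 this is the raw flux/substrate definition. A zero
    substrate abundance yields a non-estimable result instead of dividing.
    """
    if not 0 < label_plateau <= 1.0 + 1e-9:
        raise ValueError("label_plateau must be in (0, 1]")
    if substrate_a0_pct <= 0:
        return RateEstimate(
            reaction, kind, site_name, slope_pct_per_h, slope_stderr,
            substrate_a0_pct, math.nan, math.nan, False, replicate,
        )
    denom = substrate_a0_pct * label_plateau
    return RateEstimate(
        reaction, kind, site_name, slope_pct_per_h, slope_stderr,
        substrate_a0_pct, slope_pct_per_h / denom, slope_stderr / denom,
        True, replicate,
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class AcetylationKineticsModel:
    """Site-specific acetylation kinetics fitted to a species time course.

    Parameters
    ----------
    data :
        Tidy table with columns ``time_min, replicate, state_id,
        abundance_pct``; ``state_id`` is a string over U/L/H per site (U =
        unmodified i.e. chemically acetylated, L = pre-existing light acetyl,
        H = metabolically acquired heavy acetyl). Per (time, replicate) the
        abundances must cover all 3**n states and sum to ~100.
    peptide :
        Optional peptide spec providing site display names (K18, K23, ...).
    """

    def __init__(self, data: pd.DataFrame, peptide: PeptideSpec | None = None):
        required = {"time_min", "replicate", "state_id", "abundance_pct"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"kinetics input missing columns: {sorted(missing)}")
        states = sorted(set(data["state_id"]))
        n_sites = len(states[0])
        if set(states) != set(state_strings(n_sites)):
            raise ValueError(
                f"state ids do not cover all {3 ** n_sites} states over {n_sites} sites"
            )
        sums = data.groupby(["time_min", "replicate"])["abundance_pct"].sum()
        if not np.allclose(sums, 100.0, atol=1e-6):
            bad = sums[~np.isclose(sums, 100.0, atol=1e-6)]
            raise ValueError(
                f"abundances do not sum to 100% at {len(bad)} (time, replicate) points"
            )
        self.data = data.copy()
        self.n_sites = n_sites
        self.peptide = peptide
        self.site_names = (
            peptide.site_names if peptide is not None
            else tuple(f"site{i}" for i in range(n_sites))
        )
        self.network = build_network(n_sites)

    # -- helpers -----------------------------------------------------------

    def _wide(self, replicate) -> pd.DataFrame:
        block = self.data[self.data["replicate"] == replicate]
        wide = block.pivot_table(
            index="time_min", columns="state_id", values="abundance_pct", aggfunc="mean"
        ).sort_index()
        return wide

    @staticmethod
    def _class_states(n_sites: int, pattern: tuple[bool, ...]) -> list[str]:
        """States whose acetylation pattern (site occupied or not) matches."""
        out = []
        for s in state_strings(n_sites):
            if tuple(c != "U" for c in s) == pattern:
                out.append(s)
        return out

    def fit(
        self,
        window_h: float = 4.0,
        max_flux_points: int = 4,
        per_replicate: bool = True,
        label_plateau: float | None = None,
    ) -> "AcetylationKineticsResults":
        """Fit growth/decay curves, turnover and reaction rates.

        ``label_plateau=None`` estimates the acetyl-CoA heavy plateau from the
        growth fits (mean single-site plateau p); pass 1.0 for the raw
        flux/substrate rate definition.
        """
        replicates = sorted(self.data["replicate"].unique())
        if not per_replicate:
            pooled = (
                self.data.groupby(["time_min", "state_id"], as_index=False)["abundance_pct"]
                .mean()
            )
            pooled["replicate"] = "pooled"
            self = AcetylationKineticsModel(pooled, self.peptide)
            replicates = ["pooled"]

        growth_rows, decay_rows, turnover_rows, rate_rows = [], [], [], []
        n = self.n_sites
        patterns = [
            p for p in itertools.product((False, True), repeat=n) if any(p)
        ]
        wides = {rep: self._wide(rep) for rep in replicates}

        # --- stage 1: free (p, k) fits per replicate, class and site -------
        cached: list[dict] = []
        for rep in replicates:
            wide = wides[rep]
            t = wide.index.to_numpy(dtype=float)
            for pattern in patterns:
                cls_states = self._class_states(n, pattern)
                cls_label = "+".join(
                    self.site_names[i] for i, occ in enumerate(pattern) if occ
                ) + "ac"
                cls_total = wide[cls_states].sum(axis=1).to_numpy()
                for i, occ in enumerate(pattern):
                    if not occ:
                        continue
                    heavy = wide[[s for s in cls_states if s[i] == "H"]].sum(axis=1).to_numpy()
                    light = wide[[s for s in cls_states if s[i] == "L"]].sum(axis=1).to_numpy()
                    try:
                        mask, f = label_fraction(heavy, light)
                    except ValueError:
                        continue
                    if np.count_nonzero(mask) < 4:
                        continue
                    # noise can push near-zero channels slightly negative
                    # upstream; the fraction is clipped onto its physical range
                    f = np.clip(f, 0.0, 1.0)
                    fit = fit_growth(t[mask], f[mask])
                    cached.append({
                        "replicate": rep, "species_class": cls_label,
                        "site": self.site_names[i], "pattern": pattern,
                        "t": t[mask], "f": f[mask], "fit": fit,
                        "class_abundance": float(np.mean(cls_total)),
                    })

        # --- stage 2: shared acetyl-CoA plateau and constrained refits -----
        # All sites exchange label against the same acetyl-CoA pool, so the
        # growth curves share one plateau; it is pooled over every free fit by
        # inverse variance, which discounts ridge-degenerate fits of slow
        # sites whose curves stay far from saturation.
        w_sum = p_sum = 0.0
        for c in cached:
            fit = c["fit"]
            if fit.ok and np.isfinite(fit.sigma_p):
                w = 1.0 / max(fit.sigma_p, 1e-6) ** 2
                w_sum += w
                p_sum += w * fit.p
        shared_plateau = min(p_sum / w_sum, 1.0) if w_sum > 0 else 1.0

        for c in cached:
            refit = fit_growth_fixed_plateau(c["t"], c["f"], shared_plateau)
            fit = c["fit"]
            growth_rows.append({
                "replicate": c["replicate"], "species_class": c["species_class"],
                "site": c["site"], "p": fit.p, "k_per_h": fit.k,
                "sigma_p": fit.sigma_p, "sigma_k": fit.sigma_k,
                "t_half_min": fit.t_half_min,
                "k_shared_per_h": refit.k, "sigma_k_shared": refit.sigma_k,
                "t_half_shared_min": refit.t_half_min,
                "ok": fit.ok, "ok_shared": refit.ok,
            })
            if refit.ok and sum(c["pattern"]) == 1:
                tv = turnover(refit.k, c["class_abundance"], c["species_class"])
                turnover_rows.append({
                    "replicate": c["replicate"], "species": c["species_class"],
                    "site": c["site"], "k_per_h": tv.k_per_h,
                    "abundance_pct": tv.abundance_pct,
                    "turnover_pct_per_h": tv.turnover_pct_per_h,
                })

        # --- decay fit for the fully acetylated class ----------------------
        for rep in replicates:
            wide = wides[rep]
            t = wide.index.to_numpy(dtype=float)
            if n >= 2:
                full = tuple([True] * n)
                cls_states = self._class_states(n, full)
                cls_total = wide[cls_states].sum(axis=1).to_numpy()
                all_light = wide["L" * n].to_numpy()
                with np.errstate(invalid="ignore", divide="ignore"):
                    r_pct = np.where(cls_total > 0, all_light / cls_total * 100.0, np.nan)
                if np.count_nonzero(np.isfinite(r_pct)) >= 3:
                    dfit = fit_decay_fixed_intercept(t, r_pct)
                    decay_rows.append({
                        "replicate": rep, "species_class": "+".join(self.site_names) + "ac",
                        "k_per_h": dfit.k, "sigma_k": dfit.sigma_k,
                        "t_half_min": dfit.t_half_min, "ok": dfit.ok,
                    })
                    if dfit.ok:
                        a_mean = float(np.mean(cls_total))
                        turnover_rows.append({
                            "replicate": rep, "species": "+".join(self.site_names) + "ac",
                            "site": "total", "k_per_h": dfit.k, "abundance_pct": a_mean,
                            "turnover_pct_per_h": dfit.k * a_mean,
                        })

        # --- stage 3: reaction rates from initial fluxes -------------------
        lam = shared_plateau if label_plateau is None else label_plateau
        lam = min(max(lam, 1e-6), 1.0)
        for rep in replicates:
            wide = wides[rep]
            t = wide.index.to_numpy(dtype=float)
            fluxes: dict[str, FluxResult] = {}

            def flux_of(state: str) -> FluxResult:
                if state not in fluxes:
                    fluxes[state] = initial_flux(
                        t, wide[state].to_numpy(), window_h, max_flux_points
                    )
                return fluxes[state]

            seen_deacet: set[str] = set()
            for rxn in self.network.estimable():
                if rxn.kind == "acetylation":
                    # heavy products are exactly absent before the label
                    # switch, so the product slope is pinned through (0, 0)
                    prod_flux = initial_flux(
                        t, wide[rxn.product].to_numpy(), window_h,
                        max_flux_points, intercept_at=0.0,
                    )
                    sub_flux = flux_of(rxn.substrate)
                    est = reaction_rate(
                        prod_flux.slope_pct_per_h, sub_flux.intercept_pct, lam,
                        prod_flux.stderr, rxn.label, rxn.kind,
                        self.site_names[rxn.site], rep,
                    )
                else:
                    # one total-deacetylation estimate per light substrate.
                    # The flux is measured on the substrate's light-retention
                    # ratio within its occupancy class (substrate / all label
                    # variants of the same acetylation pattern): class
                    # abundance is constant at steady state, so the ratio
                    # decays with exactly the substrate's deacetylation flux
                    # while common-mode intensity noise cancels.
                    if rxn.substrate in seen_deacet:
                        continue
                    seen_deacet.add(rxn.substrate)
                    pattern = tuple(c != "U" for c in rxn.substrate)
                    cls_states = self._class_states(n, pattern)
                    cls_total = wide[cls_states].sum(axis=1).to_numpy()
                    sub_traj = wide[rxn.substrate].to_numpy()
                    with np.errstate(invalid="ignore", divide="ignore"):
                        ratio = np.where(cls_total > 0, sub_traj / cls_total, np.nan)
                    # the light-retention ratio is exactly 100% at t = 0
                    ratio_flux = initial_flux(
                        t, ratio * 100.0, window_h, max_flux_points,
                        intercept_at=100.0,
                    )
                    a0 = flux_of(rxn.substrate).intercept_pct
                    species_slope = ratio_flux.slope_pct_per_h / 100.0 * a0
                    species_slope_se = ratio_flux.stderr / 100.0 * a0
                    n_light = rxn.substrate.count("L")
                    site_name = (
                        self.site_names[rxn.site] if n_light == 1 else "total"
                    )
                    est = reaction_rate(
                        -species_slope, a0, lam,
                        species_slope_se, rxn.label, rxn.kind, site_name, rep,
                    )
                rate_rows.append({
                    "replicate": rep, "reaction": est.reaction, "kind": est.kind,
                    "site": est.site_name, "substrate": rxn.substrate,
                    "slope_pct_per_h": est.slope_pct_per_h,
                    "slope_stderr": est.slope_stderr,
                    "substrate_a0_pct": est.substrate_a0_pct,
                    "rate_per_h": est.rate_per_h, "rate_stderr": est.rate_stderr,
                    "estimable": est.estimable, "label_plateau": lam,
                })

        return AcetylationKineticsResults(
            model=self,
            growth_fits=pd.DataFrame(growth_rows),
            decay_fits=pd.DataFrame(decay_rows),
            turnover=pd.DataFrame(turnover_rows),
            rates=pd.DataFrame(rate_rows),
        )


@dataclass
class AcetylationKineticsResults:
    """Fitted kinetics: per-replicate tables and aggregated summaries."""

    model: AcetylationKineticsModel
    growth_fits: pd.DataFrame
    decay_fits: pd.DataFrame
    turnover: pd.DataFrame
    rates: pd.DataFrame

    @staticmethod
    def _agg(df: pd.DataFrame, keys: list[str], cols: list[str]) -> pd.DataFrame:
        if df.empty:
            return df
        g = df.groupby(keys)[cols]
        out = g.agg(["mean", "std"])
        out.columns = [f"{c}_{s}" for c, s in out.columns]
        out["n_replicates"] = df.groupby(keys).size()
        return out.reset_index()

    @property
    def growth_summary(self) -> pd.DataFrame:
        ok = self.growth_fits[self.growth_fits["ok"] & self.growth_fits["ok_shared"]]
        return self._agg(
            ok, ["species_class", "site"],
            ["p", "k_per_h", "t_half_min", "k_shared_per_h", "t_half_shared_min"],
        )

    @property
    def decay_summary(self) -> pd.DataFrame:
        ok = self.decay_fits[self.decay_fits["ok"]] if not self.decay_fits.empty else self.decay_fits
        return self._agg(ok, ["species_class"], ["k_per_h", "t_half_min"])

    @property
    def turnover_summary(self) -> pd.DataFrame:
        return self._agg(
            self.turnover, ["species", "site"],
            ["k_per_h", "abundance_pct", "turnover_pct_per_h"],
        )

    @property
    def rates_summary(self) -> pd.DataFrame:
        est = self.rates[self.rates["estimable"]]
        return self._agg(
            est, ["reaction", "kind", "site", "substrate"],
            ["rate_per_h", "substrate_a0_pct"],
        )

    @property
    def label_plateau(self) -> float:
        if self.rates.empty:
            return float("nan")
        return float(self.rates["label_plateau"].mean())

    def summary(self) -> str:
        lines = ["Acetylation kinetics summary", "=" * 60]
        pep = self.model.peptide.name if self.model.peptide else f"{self.model.n_sites}-site peptide"
        lines.append(f"peptide: {pep}   acetyl-CoA heavy plateau: {self.label_plateau:.3f}")
        lines.append("")
        lines.append("Site half-lives (growth fits, f = H/(H+L)):")
        lines.append(self.growth_summary.to_string(index=False))
        if not self.decay_fits.empty:
            lines.append("")
            lines.append("Fully acetylated species (fixed-intercept decay):")
            lines.append(self.decay_summary.to_string(index=False))
        lines.append("")
        lines.append("Abundance-corrected turnover (k*A):")
        lines.append(self.turnover_summary.to_string(index=False))
        lines.append("")
        lines.append("Reaction rates (initial flux / substrate, plateau-corrected):")
        lines.append(self.rates_summary.to_string(index=False))
        return "\n".join(lines)
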