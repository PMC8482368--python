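"""Resolve MS1-isobaric positional isomers from site-diagnostic fragment ions.

Positional isomers (same label multiset on different lysines) are isobaric at
the precursor level but their b/y fragments containing a subset of the sites
differ in mass. For every fragment (series, index) the group members fall into
mass-equivalence *classes*; the relative intensity of each class's peak
estimates the summed fraction of its members. Stacking these linear equations
over both ion series and solving under the simplex constraint yields the
per-member fractions — for two-member groups this reduces to the simple
intensity ratio of the member-unique ("diagnostic") ions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .constants import DEFAULT_ATOMS, AtomTable
from .mass_model import FragmentIon, IsobaricGroup, PeptideSpec, fragment_mz

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentClass",
    "DiagnosticSet",
    "IsomerFractions",
    "fragment_classes",
    "find_diagnostic_ions",
    "site_fractions",
    "apportion_group_abundance",
    "resolve_table",
]


@dataclass(frozen=True)
class FragmentClass:
    """One distinct fragment m/z shared by a subset of group members."""

    series: str
    index: int
    charge: int
    mz: float
    members: tuple[str, ...]  # display ids

    @property
    def label(self) -> str:
        ion = f"{self.series}{self.index}" + (f"z{self.charge}" if self.charge != 1 else "")
        return f"{ion}/{'+'.join(self.members)}"


def fragment_classes(
    group: IsobaricGroup,
    series: Sequence[str] = ("b", "y"),
    charge: int = 1,
    fragment_tol_ppm: float = 10.0,
    atoms: AtomTable = DEFAULT_ATOMS,
) -> list[FragmentClass]:
    """Informative fragment ions of a group, clustered into mass classes.

    Only fragments with >= 2 distinct classes (i.e. carrying positional
    information) are returned.
    """
    if not group.members:
        raise ValueError("empty isobaric group")
    pep = group.members[0].peptide
    n = len(pep.sequence)
    out: list[FragmentClass] = []
    for s in series:
        for idx in range(1, n):
            ions = [fragment_mz(m, s, idx, charge, atoms) for m in group.members]
            classes: list[list[tuple[float, str]]] = []
            for ion, member in sorted(
                zip(ions, group.members), key=lambda t: t[0].mz
            ):
                tol = fragment_tol_ppm * 1e-6 * ion.mz
                if classes and ion.mz - classes[-1][-1][0] <= tol:
                    classes[-1].append((ion.mz, member.display_id))
                else:
                    classes.append([(ion.mz, member.display_id)])
            if len(classes) < 2:
                continue
            for cls in classes:
                mzs = [mz for mz, _m in cls]
                out.append(
                    FragmentClass(
                        s, idx, charge, float(np.mean(mzs)), tuple(m for _mz, m in cls)
                    )
                )
    return out


@dataclass(frozen=True)
class DiagnosticSet:
    """Per-member fragment ions unique to that member within its group."""

    group: IsobaricGroup
    ions: Mapping[str, tuple[FragmentIon, ...]]  # display id -> diagnostic ions

    def unresolvable_members(self) -> tuple[str, ...]:
        return tuple(m for m, ions in self.ions.items() if not ions)


def find_diagnostic_ions(
    group: IsobaricGroup,
    series: Sequence[str] = ("b", "y"),
    charge: int = 1,
    fragment_tol_ppm: float = 10.0,
    atoms: AtomTable = DEFAULT_ATOMS,
) -> DiagnosticSet:
    """Fragment ions whose m/z separates one member from *all* other members.

    Members without any strictly unique ion are flagged (empty tuple); such
    interior-site members of larger groups can still be quantified through the
    fragment-class linear system in :func:`site_fractions`.
    """
    classes = fragment_classes(group, series, charge, fragment_tol_ppm, atoms)
    diag: dict[str, list[FragmentIon]] = {m.display_id: [] for m in group.members}
    if len(group.members) == 1:
        return DiagnosticSet(group, {group.members[0].display_id: ()})
    member_by_id = {m.display_id: m for m in group.members}
    for cls in classes:
        if len(cls.members) == 1:
            mid = cls.members[0]
            diag[mid].append(
                fragment_mz(member_by_id[mid], cls.series, cls.index, cls.charge, atoms)
            )
    return DiagnosticSet(group, {m: tuple(v) for m, v in diag.items()})


@dataclass(frozen=True)
class IsomerFractions:
    """Per-member fractions of an isobaric group, with per-series estimates."""

    group_id: str
    fractions: Mapping[str, float]
    per_series: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dispersion: float = 0.0
    resolved: bool = True
    consistent: bool = True


def _solve_simplex_lsq(
    members: Sequence[str],
    equations: list[tuple[tuple[str, ...], float, float]],
) -> np.ndarray | None:
    """Weighted least squares for member fractions on the probability simplex.

    ``equations`` rows are (member subset, target fraction, weight). Returns
    None when the system (plus the sum-to-one constraint) does not determine
    all fractions.
    """
    n = len(members)
    idx = {m: i for i, m in enumerate(members)}
    rows, targets, weights = [], [], []
    for subset, frac, w in equations:
        row = np.zeros(n)
        for m in subset:
            row[idx[m]] = 1.0
        rows.append(row)
        targets.append(frac)
        weights.append(w)
    if not rows:
        return None
    big = max(weights) * 1e3
    A = np.vstack(rows + [np.ones(n)])
    b = np.array(targets + [1.0])
    w = np.sqrt(np.array(weights + [big]))
    if np.linalg.matrix_rank(A) < n:
        return None
    Aw, bw = A * w[:, None], b * w
    x, *_ = np.linalg.lstsq(Aw, bw, rcond=None)
    if np.any(x < -1e-9) or np.any(x > 1.0 + 1e-9):
        x = lsq_linear(Aw, bw, bounds=(0.0, 1.0), tol=1e-14).x
    x = np.clip(x, 0.0, 1.0)
    total = x.sum()
    return x / total if total > 0 else None


def site_fractions(
    group: IsobaricGroup,
    intensities: Mapping[str, float],
    fragment_tol_ppm: float = 10.0,
    charge: int = 1,
    series: Sequence[str] = ("b", "y"),
    dispersion_threshold: float = 0.15,
    atoms: AtomTable = DEFAULT_ATOMS,
) -> IsomerFractions:
    """Estimate member fractions from fragment-class intensities.

    ``intensities`` maps fragment-class labels (``"b3/V"``, ``"y6/K5+K8"``
    style, as produced by :class:`FragmentClass`) to non-negative intensities.
    Per-series estimates are computed where a series alone determines the
    fractions; the final estimate solves the stacked system weighted by
    fragment intensity (for fully diagnostic groups this equals the
    intensity-weighted mean over series). The dispersion between per-series
    estimates is reported and flagged against ``dispersion_threshold``.
    """
    members = [m.display_id for m in group.members]
    if len(members) == 1:
        return IsomerFractions(group.group_id, {members[0]: 1.0})
    if any(v < 0 for v in intensities.values()):
        raise ValueError("fragment intensities must be non-negative")

    classes = fragment_classes(group, series, charge, fragment_tol_ppm, atoms)
    by_fragment: dict[tuple[str, int], list[FragmentClass]] = {}
    for cls in classes:
        by_fragment.setdefault((cls.series, cls.index), []).append(cls)

    def equations_for(series_filter: str | None):
        eqs = []
        for (s, _idx), cls_list in by_fragment.items():
            if series_filter is not None and s != series_filter:
                continue
            vals = [float(intensities.get(c.label, 0.0)) for c in cls_list]
            total = sum(vals)
            if total <= 0:
                continue
            for c, v in zip(cls_list, vals):
                eqs.append((c.members, v / total, total))
        return eqs

    all_eqs = equations_for(None)
    if not all_eqs:
        logger.warning("group %s: all diagnostic intensities zero; unresolvable", group.group_id)
        return IsomerFractions(
            group.group_id,
            {m: float("nan") for m in members},
            resolved=False,
            consistent=False,
        )

    combined = _solve_simplex_lsq(members, all_eqs)
    if combined is None:
        return IsomerFractions(
            group.group_id,
            {m: float("nan") for m in members},
            resolved=False,
            consistent=False,
        )

    per_series: dict[str, dict[str, float]] = {}
    for s in series:
        eqs = equations_for(s)
        sol = _solve_simplex_lsq(members, eqs) if eqs else None
        if sol is not None:
            per_series[s] = dict(zip(members, sol.tolist()))
    dispersion = 0.0
    if len(per_series) >= 2:
        mats = np.array([[est[m] for m in members] for est in per_series.values()])
        dispersion = float(np.max(mats.max(axis=0) - mats.min(axis=0)))
    consistent = dispersion <= dispersion_threshold
    if not consistent:
        logger.warning(
            "group %s: b/y fraction estimates disagree by %.3f (> %.2f)",
            group.group_id, dispersion, dispersion_threshold,
        )
    return IsomerFractions(
        group.group_id,
        dict(zip(members, combined.tolist())),
        per_series=per_series,
        dispersion=dispersion,
        resolved=True,
        consistent=consistent,
    )


def apportion_group_abundance(
    group_abundance: float,
    fractions: IsomerFractions,
) -> dict[str, float]:
    """Split a group's MS1 abundance over its members; conserves the total."""
    if not fractions.resolved:
        raise ValueError(f"group {fractions.group_id}: fractions are unresolved")
    fr = fractions.fractions
    total = sum(fr.values())
    if total <= 0:
        raise ValueError(f"group {fractions.group_id}: zero total fraction")
    return {m: group_abundance * f / total for m, f in fr.items()}


def resolve_table(
    ms1_abundances: pd.DataFrame,
    ms2_intensities: pd.DataFrame | None,
    groups: Sequence[IsobaricGroup],
    fragment_tol_ppm: float = 10.0,
    charge: int = 1,
    dispersion_threshold: float = 0.15,
    atoms: AtomTable = DEFAULT_ATOMS,
) -> pd.DataFrame:
    """Apportion per-channel MS1 abundances into per-isotopologue abundances.

    ``ms1_abundances`` needs columns ``time_min, replicate, channel_id,
    abundance_pct`` (channel_id = isobaric group id); ``ms2_intensities``
    needs ``time_min, replicate, group_id, ion_label, intensity``. Groups
    whose fragments are all zero at a (time, replicate) are split uniformly
    and flagged ``resolved=False`` — in practice this only happens when the
    group's MS1 abundance is itself ~0 (e.g. heavy species before labeling).
    """
    by_id = {g.group_id: g for g in groups}
    unknown = set(ms1_abundances["channel_id"]) - set(by_id)
    if unknown:
        raise ValueError(f"MS1 channels without a matching group: {sorted(unknown)}")
    rows = []
    ms2_index: dict[tuple, pd.DataFrame] = {}
    if ms2_intensities is not None and len(ms2_intensities):
        for key, block in ms2_intensities.groupby(["time_min", "replicate", "group_id"]):
            ms2_index[key] = block
    for (_t, _r), block in ms1_abundances.groupby(["time_min", "replicate"], sort=False):
        for _, rec in block.iterrows():
            g = by_id[rec["channel_id"]]
            abundance = float(rec["abundance_pct"])
            if len(g.members) == 1:
                member_abund = {g.members[0].display_id: abundance}
                resolved = True
            else:
                frag_block = ms2_index.get((_t, _r, g.group_id))
                intens = (
                    dict(zip(frag_block["ion_label"], frag_block["intensity"]))
                    if frag_block is not None
                    else {}
                )
                fr = site_fractions(
                    g, intens, fragment_tol_ppm, charge,
                    dispersion_threshold=dispersion_threshold, atoms=atoms,
                )
                if fr.resolved:
                    member_abund = apportion_group_abundance(abundance, fr)
                    resolved = True
                else:
                    member_abund = {
                        m.display_id: abundance / len(g.members) for m in g.members
                    }
                    resolved = False
            for m in g.members:
                rows.append(
                    {
                        "time_min": _t,
                        "replicate": _r,
                        "isotopologue": m.display_id,
                        "state_id": m.state_id,
                        "abundance_pct": member_abund[m.display_id],
                        "resolved": resolved,
                    }
                )
    return pd.DataFrame(rows)
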