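"""Natural isotope abundance correction of MS1 channel intensities.

Each isotopologue channel receives signal not only from its own species but
also from the natural-isotope satellites of lighter species (chiefly two
natural 13C atoms shifting a species by +2.0067 Da, exactly the spacing
between the light and heavy metabolic acetyl channels). The correction builds,
per species, the theoretical isotope pattern of its *unlabeled* atoms (labeled
13C/2H positions carry no natural variation), maps each satellite onto the
channel grid within a coalescence tolerance, and inverts the resulting
per-species ("skewed") correction matrix.

The matrix is lower-triangular when channels are ordered by ascending mass
(natural satellites only add mass), so the exact inverse is a forward
substitution; a non-negative least-squares fallback is available for
ill-conditioned designs or sub-unity label purity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

from .constants import DEFAULT_ATOMS, AtomTable
from .mass_model import Formula, IsobaricGroup, PeptideSpec, enumerate_isotopologues, group_isobaric

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelSpec",
    "CorrectionMatrix",
    "IsotopePeak",
    "natural_isotope_distribution",
    "build_correction_matrix",
    "channels_for_peptide",
    "correct_intensities",
    "correct_table",
    "normalize_abundances",
]


@dataclass(frozen=True)
class IsotopePeak:
    """One natural-isotope satellite: exact mass offset (Da) and probability."""

    mass_offset: float
    probability: float


@dataclass(frozen=True)
class ChannelSpec:
    """An MS1 quantification channel (one isotopologue or isobaric group)."""

    channel_id: str
    neutral_mass: float
    formula: Formula

    def mz(self, charge: int, atoms: AtomTable = DEFAULT_ATOMS) -> float:
        return (self.neutral_mass + charge * atoms.proton) / charge


def _element_peaks(
    n_atoms: int,
    isotopes: Sequence[tuple[float, float]],
    max_shift: int,
) -> list[tuple[int, float, float]]:
    """Substitution patterns for one element: (n_subs, mass_offset, probability).

    ``isotopes`` holds (mass_shift, abundance) per minor isotope. Probabilities
    follow the multinomial over the element's n_atoms with at most
    ``max_shift`` substituted atoms in total.
    """
    if n_atoms < 0:
        raise ValueError(f"negative atom count: {n_atoms}")
    base_p = 1.0 - sum(p for _d, p in isotopes)
    # iterate isotope by isotope, choosing k substitutions of each
    states = [(0, 0.0, 1.0, n_atoms)]  # subs, offset, prob(excluding base), remaining
    for delta, p in isotopes:
        new_states = []
        for subs, off, prob, rem in states:
            for k in range(0, min(rem, max_shift - subs) + 1):
                new_states.append(
                    (subs + k, off + k * delta, prob * math.comb(rem, k) * p**k, rem - k)
                )
        states = new_states
    out = []
    for subs, off, prob, rem in states:
        out.append((subs, off, prob * base_p**rem))
    return out


def natural_isotope_distribution(
    formula: Formula,
    max_shift: int = 6,
    atoms: AtomTable = DEFAULT_ATOMS,
    label_purity: Mapping[str, float] | None = None,
) -> list[IsotopePeak]:
    """Theoretical isotope pattern of a formula's unlabeled atoms.

    Returns peaks (exact mass offset from the monoisotopic species, summed
    probability) for every natural-isotope composition with at most
    ``max_shift`` substituted atoms; peaks with identical offsets are merged.
    Probabilities sum to <= 1 and approach 1 as ``max_shift`` grows.

    ``label_purity`` optionally maps a labeled-isotope symbol (e.g. ``"13C"``)
    to its isotopic purity q < 1; impure labeled atoms then contribute peaks
    at *negative* offsets (a 12C where a 13C was intended), handled like
    natural satellites.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    convolved: dict[tuple[int, float], float] = {(0, 0.0): 1.0}

    def convolve(elem_peaks: list[tuple[int, float, float]]) -> None:
        nonlocal convolved
        nxt: dict[tuple[int, float], float] = {}
        for (subs, off), prob in convolved.items():
            for s2, o2, p2 in elem_peaks:
                if subs + s2 > max_shift or p2 == 0.0:
                    continue
                key = (subs + s2, round(off + o2, 9))
                nxt[key] = nxt.get(key, 0.0) + prob * p2
        convolved = nxt

    for elem, count in sorted(formula.unlabeled.items()):
        if count < 0:
            raise ValueError(f"negative atom count for {elem!r}")
        minors = atoms.minor_isotopes(elem)
        if not minors or count == 0:
            continue
        convolve(_element_peaks(count, [(d, p) for _i, d, p in minors], max_shift))

    if label_purity:
        for iso_sym, q in label_purity.items():
            count = formula.labeled.get(iso_sym, 0)
            if count == 0 or q >= 1.0:
                continue
            if not 0.0 < q <= 1.0:
                raise ValueError(f"purity of {iso_sym!r} out of (0, 1]: {q}")
            # each impure labeled atom reverts to its principal isotope
            elem = iso_sym.lstrip("0123456789")
            delta = atoms.mass(elem) - atoms.mass(iso_sym)
            convolve(_element_peaks(count, [(delta, 1.0 - q)], max_shift))

    merged: dict[float, float] = {}
    for (_subs, off), prob in convolved.items():
        merged[off] = merged.get(off, 0.0) + prob
    return [IsotopePeak(off, p) for off, p in sorted(merged.items())]


@dataclass(frozen=True)
class CorrectionMatrix:
    """Square per-species correction matrix over mass-ordered channels.

    Entry (i, j) is the fraction of species j's theoretical isotope pattern
    landing on channel i. Columns sum to <= 1; the diagonal holds each
    species' monoisotopic fraction.
    """

    matrix: np.ndarray
    channels: tuple[ChannelSpec, ...]
    charge: int
    coalescence_tol: float

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return tuple(c.channel_id for c in self.channels)

    @property
    def is_lower_triangular(self) -> bool:
        return bool(np.allclose(self.matrix, np.tril(self.matrix)))


def build_correction_matrix(
    channels: Sequence[ChannelSpec],
    coalescence_tol: float = 0.003,
    charge: int = 2,
    max_shift: int = 6,
    atoms: AtomTable = DEFAULT_ATOMS,
    label_purity: Mapping[str, float] | None = None,
) -> CorrectionMatrix:
    """Build the per-species correction matrix for a channel set.

    A satellite of species j is attributed to channel i when its exact neutral
    mass lies within ``coalescence_tol * charge`` (Da) of channel i's neutral
    mass — the tolerance is specified on the m/z axis, mirroring the EIC
    extraction window, and scaled back to neutral mass.
    """
    if coalescence_tol < 0:
        raise ValueError("coalescence_tol must be >= 0")
    chans = sorted(channels, key=lambda c: c.neutral_mass)
    ids = [c.channel_id for c in chans]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate channel ids")
    tol_neutral = coalescence_tol * charge
    masses = np.array([c.neutral_mass for c in chans])
    if np.any(np.diff(masses) <= tol_neutral):
        close = np.argmin(np.diff(masses))
        raise ValueError(
            f"channels {ids[close]!r} and {ids[close + 1]!r} are closer than the "
            f"coalescence tolerance ({tol_neutral:.4f} Da neutral); design unresolvable"
        )
    n = len(chans)
    M = np.zeros((n, n))
    for j, ch in enumerate(chans):
        for peak in natural_isotope_distribution(
            ch.formula, max_shift=max_shift, atoms=atoms, label_purity=label_purity
        ):
            target = ch.neutral_mass + peak.mass_offset
            i = int(np.argmin(np.abs(masses - target)))
            if abs(masses[i] - target) <= tol_neutral:
                M[i, j] += peak.probability
    return CorrectionMatrix(M, tuple(chans), charge, coalescence_tol)


def channels_for_peptide(
    spec: PeptideSpec,
    charge: int = 2,
    grouping_tol: float = 0.005,
    atoms: AtomTable = DEFAULT_ATOMS,
) -> tuple[list[ChannelSpec], list[IsobaricGroup]]:
    """MS1 channels (one per isobaric group) for a peptide's isotopologues.

    Members of an isobaric group share a label multiset and hence an elemental
    formula, so the group's isotope pattern is that of any member.
    """
    groups = group_isobaric(enumerate_isotopologues(spec), charge=charge, tol=grouping_tol, atoms=atoms)
    chans = []
    for g in groups:
        rep = g.members[0]
        chans.append(ChannelSpec(g.group_id, rep.mass(atoms), rep.formula()))
    return chans, groups


def correct_intensities(
    measured: np.ndarray,
    cm: CorrectionMatrix,
    clamp_negative: bool = True,
    method: str = "triangular",
) -> np.ndarray:
    """Solve M x = measured for the true channel intensities.

    ``method='triangular'`` uses exact forward substitution (requires the
    lower-triangular structure that ascending-mass ordering guarantees);
    ``method='nnls'`` solves the non-negative least-squares problem instead.
    Negative solution elements (noise-driven over-subtraction) are clamped to
    zero and logged when ``clamp_negative`` is set.
    """
    y = np.asarray(measured, dtype=float)
    M = cm.matrix
    if y.shape != (M.shape[0],):
        raise ValueError(f"measured vector length {y.shape} does not match {M.shape[0]} channels")
    if np.any(y < 0):
        raise ValueError("measured intensities must be non-negative")
    diag = np.diag(M)
    if np.any(diag <= 1e-12):
        raise ValueError("singular correction matrix (zero diagonal element)")
    if method == "nnls":
        x, _res = nnls(M, y)
        return x
    if method != "triangular":
        raise ValueError(f"unknown method {method!r}")
    if not cm.is_lower_triangular:
        raise ValueError(
            "correction matrix is not lower-triangular (label impurity enabled?); "
            "use method='nnls'"
        )
    cond = np.linalg.cond(M)
    if cond > 1e12:
        raise ValueError(f"ill-conditioned correction matrix (cond={cond:.2e})")
    x = solve_triangular(M, y, lower=True)
    if clamp_negative and np.any(x < 0):
        bad = [cm.channels[i].channel_id for i in np.where(x < 0)[0]]
        logger.warning("clamped negative corrected intensities to 0 for channels %s", bad)
        x = np.clip(x, 0.0, None)
    return x


def correct_table(
    df: pd.DataFrame,
    cm: CorrectionMatrix,
    value_col: str = "intensity",
    method: str = "triangular",
) -> pd.DataFrame:
    """Apply the correction per (time_min, replicate) block of a channel table.

    Expects columns ``time_min, replicate, channel_id, <value_col>``; returns
    a copy with an added ``intensity_corrected`` column.
    """
    required = {"time_min", "replicate", "channel_id", value_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"channel table missing columns: {sorted(missing)}")
    ids = list(cm.channel_ids)
    unknown = set(df["channel_id"]) - set(ids)
    if unknown:
        raise ValueError(f"unknown channel ids in table: {sorted(unknown)}")
    out = df.copy()
    out["intensity_corrected"] = np.nan
    for (_t, _r), block in out.groupby(["time_min", "replicate"], sort=False):
        sub = block.set_index("channel_id")[value_col]
        if set(sub.index) != set(ids):
            missing_ch = sorted(set(ids) - set(sub.index))
            raise ValueError(f"time {_t}, replicate {_r}: missing channels {missing_ch}")
        y = sub.reindex(ids).to_numpy(dtype=float)
        x = correct_intensities(y, cm, method=method)
        lut = dict(zip(ids, x))
        out.loc[block.index, "intensity_corrected"] = [
            lut[c] for c in block["channel_id"]
        ]
    return out


def normalize_abundances(
    df: pd.DataFrame,
    value_col: str = "intensity_corrected",
    group_cols: Sequence[str] = ("time_min", "replicate"),
) -> pd.DataFrame:
    """Convert corrected intensities to relative abundances (%) per group.

    Groups whose total intensity is zero are flagged (``missing`` column) and
    left NaN rather than propagating 0/0.
    """
    out = df.copy()
    totals = out.groupby(list(group_cols))[value_col].transform("sum")
    out["missing"] = totals <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out["abundance_pct"] = np.where(
            out["missing"], np.nan, out[value_col] / totals * 100.0
        )
    n_missing = int(out.loc[out["missing"], group_cols[0]].nunique()) if out["missing"].any() else 0
    if n_missing:
        logger.warning("%d (time, replicate) groups had zero total intensity", n_missing)
    return out
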