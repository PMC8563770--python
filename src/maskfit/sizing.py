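"""FWHM-based semi-customised sizing: table construction and assignment.

A cohort of extracted facial parameters is reduced to a catalogue of nine
designs in two stages. A normal distribution is fitted to the cohort's
eye-to-chin distances and three hard-shell size brackets (Small / Medium
/ Large) are centred on the lower FWHM boundary, the maximum (mean), and
the upper FWHM boundary of that fit. Within each shell bracket the same
procedure applied to the nasal-spread ``sigma`` values yields three nasal
profiles (I / II / III), and the mean peak height ``A`` of the members of
each (shell, profile) cell completes the design definition: 3 x 3 = 9
semi-customised designs.

Adjacent shell brackets may overlap; a user in an overlap is assigned the
shell whose profiles best match their ``sigma``. A user outside the
brackets at either stage is flagged for the fully-customised route — a
valid outcome, not an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, NumericalError

__all__ = [
    "FWHM_FACTOR",
    "SHELL_LABELS",
    "PROFILE_LABELS",
    "NormalFitSummary",
    "SizeBracket",
    "SizingTable",
    "AssignmentResult",
    "AgreementSummary",
    "fit_normal",
    "build_size_brackets",
    "build_sizing_table",
    "assign",
    "coverage",
    "compare_param_sets",
    "reference_table",
]

#: FWHM of a normal distribution in units of its standard deviation.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

SHELL_LABELS = ("Small", "Medium", "Large")
PROFILE_LABELS = ("I", "II", "III")

#: Default bracket half-widths, calibrated to the published nine-design
#: catalogue (shell brackets span about 9 mm, profile brackets about 1.0).
DEFAULT_SHELL_HALF_WIDTH = 4.5
DEFAULT_PROFILE_HALF_WIDTH = 0.5

COHORT_COLUMNS = ("subject_id", "eye_to_chin_mm", "A_mm", "sigma_mm")


@dataclass(frozen=True)
class NormalFitSummary:
    """Moment fit of a normal distribution: mean, sample sd (n-1), FWHM."""

    mu: float
    sd: float
    fwhm: float = field(init=False)

    def __post_init__(self):
        if self.sd <= 0:
            raise NumericalError("normal fit requires positive spread")
        object.__setattr__(self, "fwhm", FWHM_FACTOR * self.sd)


@dataclass(frozen=True)
class SizeBracket:
    """A labelled closed interval with its midpoint."""

    label: str
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise InputError(
                f"bracket {self.label!r}: lower {self.lower} must be < upper {self.upper}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class SizingTable:
    """The nine-cell (3 shells x 3 nasal profiles) design catalogue.

    ``profiles`` maps each shell label to its three sigma brackets;
    ``mean_A`` and ``mean_sigma`` map (shell, profile) to the cell's mean
    peak height and mean spread.
    """

    shells: tuple[SizeBracket, ...]
    profiles: dict[str, tuple[SizeBracket, ...]]
    mean_A: dict[tuple[str, str], float]
    mean_sigma: dict[tuple[str, str], float] = field(default_factory=dict)
    n_cohort: Optional[int] = None

    def __post_init__(self):
        if len(self.shells) != 3:
            raise InputError("a sizing table has exactly 3 shell brackets")
        mids = [b.midpoint for b in self.shells]
        if not (mids[0] < mids[1] < mids[2]):
            raise InputError("shell brackets must be ordered by midpoint")
        if self.shells[0].upper >= self.shells[2].lower:
            raise InputError("non-adjacent shell brackets must not overlap")
        cells = {
            (s.label, p.label) for s in self.shells for p in self.profiles[s.label]
        }
        if len(cells) != 9:
            raise InputError(f"expected 9 (shell, profile) cells, got {len(cells)}")
        missing = cells - set(self.mean_A)
        if missing:
            raise InputError(f"mean_A missing for cells: {sorted(missing)}")

    @property
    def overlap_regions(self) -> list[tuple[str, str, float, float]]:
        """Intervals where adjacent shell brackets intersect."""
        out = []
        for a, b in zip(self.shells[:-1], self.shells[1:]):
            if b.lower < a.upper:
                out.append((a.label, b.label, b.lower, a.upper))
        return out

    def shell(self, label: str) -> SizeBracket:
        return next(s for s in self.shells if s.label == label)

    def cells(self):
        for s in self.shells:
            for p in self.profiles[s.label]:
                yield s, p

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "shells": [
                {"label": s.label, "lower": s.lower, "upper": s.upper}
                for s in self.shells
            ],
            "profiles": {
                lab: [
                    {"label": p.label, "lower": p.lower, "upper": p.upper}
                    for p in brs
                ]
                for lab, brs in self.profiles.items()
            },
            "mean_A": {f"{s}/{p}": v for (s, p), v in self.mean_A.items()},
            "mean_sigma": {f"{s}/{p}": v for (s, p), v in self.mean_sigma.items()},
            "n_cohort": self.n_cohort,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SizingTable":
        shells = tuple(SizeBracket(**s) for s in d["shells"])
        profiles = {
            lab: tuple(SizeBracket(**p) for p in brs)
            for lab, brs in d["profiles"].items()
        }

        def unkey(mapping):
            return {tuple(k.split("/")): v for k, v in mapping.items()}

        return cls(
            shells=shells,
            profiles=profiles,
            mean_A=unkey(d["mean_A"]),
            mean_sigma=unkey(d.get("mean_sigma", {})),
            n_cohort=d.get("n_cohort"),
        )

    def to_json(self, path) -> Path:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(self.to_dict(), indent=2))
        return p

    @classmethod
    def from_json(cls, path) -> "SizingTable":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_frame(self) -> pd.DataFrame:
        """Catalogue-shaped table: one row per (shell, profile) cell."""
        rows = []
        for s, p in self.cells():
            rows.append(
                {
                    "shell": s.label,
                    "eye_to_chin_from_mm": s.lower,
                    "eye_to_chin_to_mm": s.upper,
                    "eye_to_chin_midpoint_mm": s.midpoint,
                    "profile": p.label,
                    "sigma_from": p.lower,
                    "sigma_to": p.upper,
                    "sigma_mean": self.mean_sigma.get((s.label, p.label)),
                    "A_mean_mm": self.mean_A[(s.label, p.label)],
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of sizing one user: a semi-customised cell or a
    fully-customised flag, with the rule applications that led there."""

    route: str  # "SEMI_CUSTOM" or "FULLY_CUSTOM"
    shell: Optional[str]
    profile: Optional[str]
    in_overlap: bool
    rationale: tuple[str, ...]
    mean_A: Optional[float] = None

    def __post_init__(self):
        semi = self.shell is not None and self.profile is not None
        if (self.route == "SEMI_CUSTOM") != semi:
            raise ValueError(
                "route is SEMI_CUSTOM iff both shell and profile are set"
            )

    def as_dict(self) -> dict:
        return {
            "route": self.route,
            "shell": self.shell,
            "profile": self.profile,
            "in_overlap": self.in_overlap,
            "mean_A": self.mean_A,
            "rationale": list(self.rationale),
        }


@dataclass(frozen=True)
class AgreementSummary:
    """Agreement between two matched measurement sets of one parameter."""

    mean_diff: float  # mean absolute difference
    mean_diff_pct: float  # as a percentage of the first set's mean
    sd_diff: float  # sd of the signed differences
    mean_signed_diff: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise InputError("agreement summary needs n >= 1")
        if self.sd_diff < 0:
            raise ValueError("sd_diff must be non-negative")


# ---------------------------------------------------------------------------


def fit_normal(values: Sequence[float]) -> NormalFitSummary:
    """Moment fit: mu = sample mean, sd = sample standard deviation (n-1)."""
    v = np.asarray(values, dtype=float).reshape(-1)
    if v.size < 3:
        raise InputError(f"normal fit needs at least 3 values, got {v.size}")
    if np.unique(v).size < 2:
        raise NumericalError("all values identical: degenerate scale")
    sd = float(v.std(ddof=1))
    if sd <= 0:
        raise NumericalError("zero spread: degenerate scale")
    return NormalFitSummary(mu=float(v.mean()), sd=sd)


def build_size_brackets(
    values: Sequence[float],
    half_width: float,
    labels: Sequence[str] = SHELL_LABELS,
) -> tuple[SizeBracket, SizeBracket, SizeBracket]:
    """Three brackets centred on the lower FWHM boundary, the maximum, and
    the upper FWHM boundary of the fitted normal, each spanning
    ``centre ± half_width``."""
    if half_width <= 0:
        raise InputError("half_width must be positive")
    fit = fit_normal(values)
    centres = (fit.mu - fit.fwhm / 2, fit.mu, fit.mu + fit.fwhm / 2)
    if 2 * half_width >= fit.fwhm:
        raise InputError(
            f"half_width {half_width} too large: the Small and Large "
            f"brackets would overlap (FWHM = {fit.fwhm:.3g})"
        )
    return tuple(
        SizeBracket(label=lab, lower=c - half_width, upper=c + half_width)
        for lab, c in zip(labels, centres)
    )


def _as_cohort(cohort) -> pd.DataFrame:
    df = pd.DataFrame(cohort)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"cohort table is missing columns: {missing}")
    vals = df[["eye_to_chin_mm", "A_mm", "sigma_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise InputError("cohort parameters must all be positive and finite")
    return df


def build_sizing_table(
    cohort,
    shell_half_width: float = DEFAULT_SHELL_HALF_WIDTH,
    profile_half_width: float = DEFAULT_PROFILE_HALF_WIDTH,
) -> SizingTable:
    """Build the nine-design catalogue from a cohort table.

    Shell brackets come from the eye-to-chin distribution; members of each
    shell bracket (overlap members belong to both adjacent shells) supply
    the per-shell sigma distribution for the profile brackets, and the
    mean ``A`` over each (shell, profile) cell's members completes the
    cell.
    """
    df = _as_cohort(cohort)
    if len(df) < 30:
        warnings.warn(
            f"cohort has only {len(df)} records; bracket moments will be noisy",
            stacklevel=2,
        )
    shells = build_size_brackets(df["eye_to_chin_mm"], shell_half_width)
    profiles: dict[str, tuple[SizeBracket, ...]] = {}
    mean_A: dict[tuple[str, str], float] = {}
    mean_sigma: dict[tuple[str, str], float] = {}
    for shell in shells:
        members = df[
            (df["eye_to_chin_mm"] >= shell.lower)
            & (df["eye_to_chin_mm"] <= shell.upper)
        ]
        if len(members) < 3:
            raise InputError(
                f"shell {shell.label!r} has only {len(members)} members; "
                "cannot fit its sigma distribution"
            )
        brs = build_size_brackets(
            members["sigma_mm"], profile_half_width, labels=PROFILE_LABELS
        )
        profiles[shell.label] = brs
        for br in brs:
            cell = members[
                (members["sigma_mm"] >= br.lower) & (members["sigma_mm"] <= br.upper)
            ]
            if len(cell) == 0:
                raise InputError(
                    f"cell ({shell.label}, {br.label}) has no members; "
                    "cannot compute its mean A"
                )
            mean_A[(shell.label, br.label)] = float(cell["A_mm"].mean())
            mean_sigma[(shell.label, br.label)] = float(cell["sigma_mm"].mean())
    return SizingTable(
        shells=shells, profiles=profiles, mean_A=mean_A,
        mean_sigma=mean_sigma, n_cohort=len(df),
    )


def _profile_match(table: SizingTable, shell_label: str, sigma: float):
    """Containing profile brackets of a shell and the best of them
    (closest midpoint; ties to the lower-numbered profile)."""
    containing = [p for p in table.profiles[shell_label] if p.contains(sigma)]
    if not containing:
        return None, np.inf
    best = min(containing, key=lambda p: (abs(sigma - p.midpoint), p.label))
    return best, abs(sigma - best.midpoint)


def assign(params, table: SizingTable) -> AssignmentResult:
    """Assign a user to one of the nine designs or flag fully-custom.

    ``params`` needs ``eye_to_chin`` and ``sigma`` attributes (a
    :class:`~maskfit.facial_params.FacialParameters` works) or is a
    ``(eye_to_chin, sigma)`` pair.

    Rules, in order: (1) shells whose eye-to-chin range contains the user
    — none means fully-custom; (2) a single shell: pick the profile whose
    sigma range contains the user, else fully-custom; (3) an overlap of
    two shells: the shell with a containing profile wins; if both contain,
    the closer sigma midpoint wins (ties: closer shell midpoint, then the
    smaller shell); if neither contains, fully-custom.
    """
    if hasattr(params, "eye_to_chin"):
        e2c, sigma = float(params.eye_to_chin), float(params.sigma)
    else:
        e2c, sigma = map(float, params)
    if not (np.isfinite(e2c) and np.isfinite(sigma)):
        raise InputError("eye_to_chin and sigma must be finite")
    rationale = []
    shells_in = [s for s in table.shells if s.contains(e2c)]
    rationale.append(
        f"eye-to-chin {e2c:.1f} mm falls in shell(s): "
        f"{[s.label for s in shells_in] or 'none'}"
    )
    if not shells_in:
        rationale.append("outside all shell ranges -> fully-customised route")
        return AssignmentResult(
            "FULLY_CUSTOM", None, None, False, tuple(rationale)
        )
    in_overlap = len(shells_in) > 1

    candidates = []
    for s in shells_in:
        best, dist = _profile_match(table, s.label, sigma)
        if best is None:
            rationale.append(
                f"sigma {sigma:.2f} outside all {s.label} profile ranges"
            )
        else:
            rationale.append(
                f"sigma {sigma:.2f} matches {s.label} profile {best.label} "
                f"(midpoint distance {dist:.3f})"
            )
            candidates.append((s, best, dist))
    if not candidates:
        rationale.append("no shell offers a containing profile -> fully-customised")
        return AssignmentResult(
            "FULLY_CUSTOM", None, None, in_overlap, tuple(rationale)
        )
    if len(candidates) == 1:
        shell, prof, _ = candidates[0]
    else:
        # overlap with a containing profile in both shells: closest sigma
        # midpoint, then closest shell midpoint, then the smaller shell
        order = {s.label: i for i, s in enumerate(table.shells)}
        shell, prof, _ = min(
            candidates,
            key=lambda c: (c[2], abs(e2c - c[0].midpoint), order[c[0].label]),
        )
        rationale.append(
            f"overlap resolved to {shell.label} by closest sigma match"
        )
    rationale.append(f"assigned {shell.label} ({prof.label})")
    return AssignmentResult(
        "SEMI_CUSTOM", shell.label, prof.label, in_overlap, tuple(rationale),
        mean_A=table.mean_A.get((shell.label, prof.label)),
    )


def coverage(cohort, table: SizingTable, mode: str = "joint") -> float:
    """Fraction of a cohort served by the semi-customised designs.

    ``mode='joint'``: records whose assignment is SEMI_CUSTOM (eye-to-chin
    in range *and* sigma inside a profile of an eligible shell).
    ``mode='shell'``: records whose eye-to-chin alone lies within
    [Small.lower, Large.upper].
    """
    df = _as_cohort(cohort)
    if len(df) == 0:
        raise InputError("cohort is empty")
    e2c = df["eye_to_chin_mm"].to_numpy(dtype=float)
    if mode == "shell":
        lo, hi = table.shells[0].lower, table.shells[2].upper
        return float(np.mean((e2c >= lo) & (e2c <= hi)))
    if mode != "joint":
        raise InputError(f"unknown coverage mode {mode!r}")
    sig = df["sigma_mm"].to_numpy(dtype=float)
    ok = sum(
        assign((e, s), table).route == "SEMI_CUSTOM" for e, s in zip(e2c, sig)
    )
    return ok / len(df)


def compare_param_sets(set_a, set_b) -> dict[str, AgreementSummary]:
    """Per-parameter agreement between two matched measurement sets
    (e.g. the same subjects scanned by two different systems).

    Sets are matched on ``subject_id``; returns, per parameter column, the
    mean absolute difference, that as a percentage of the first set's
    mean, and the sd of the signed differences.
    """
    a, b = _as_cohort(set_a), _as_cohort(set_b)
    if len(a) != len(b):
        raise InputError(f"set sizes differ: {len(a)} vs {len(b)}")
    a = a.sort_values("subject_id").reset_index(drop=True)
    b = b.sort_values("subject_id").reset_index(drop=True)
    if not (a["subject_id"] == b["subject_id"]).all():
        raise InputError("subject_id values do not match between sets")
    out = {}
    for col in ("eye_to_chin_mm", "A_mm", "sigma_mm"):
        diffs = b[col].to_numpy(dtype=float) - a[col].to_numpy(dtype=float)
        mean_abs = float(np.mean(np.abs(diffs)))
        sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
        out[col] = AgreementSummary(
            mean_diff=mean_abs,
            mean_diff_pct=100.0 * mean_abs / float(a[col].mean()),
            sd_diff=sd,
            mean_signed_diff=float(diffs.mean()),
            n=len(diffs),
        )
    return out


def reference_table() -> SizingTable:
    """The bundled nine-design reference catalogue, as established from a
    200-participant scanned cohort."""
    from importlib.resources import files

    path = files("maskfit").joinpath("data/reference_sizing_table.json")
    return SizingTable.from_dict(json.loads(path.read_text()))
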