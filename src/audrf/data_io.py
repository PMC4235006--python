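"""Domain types and on-disk formats for tone-grid spike-count data.

The experimental substrate is trial-wise spike counts of single units recorded
on two stimulus paradigms:

* a frequency x level grid (the *frequency response area*, FRA), tones spaced
  0.1 octave apart spanning -3 to +2 octaves around the unit's estimated
  characteristic frequency, at levels from 10 to 90 dB attenuation in 5 dB
  steps;
* a level-only series at the characteristic frequency (the *rate-level
  function*, RLF), 10 to 90 dB attenuation in 10 dB steps, 20 or 50
  repetitions per level.

Levels are stored in dB **attenuation** re the maximum system output (the
acquisition coordinate; larger attenuation = quieter sound).  Sound pressure
level is a derived view requiring a calibration value:
``SPL = max_output_spl - attenuation``.

Each unit may be measured under up to three conditions -- ``control``,
``deactivated`` (contralateral inferior colliculus silenced) and ``recovery``
-- collected in a :class:`ConditionTriplet`; the unit serves as its own
control.

On disk, grids are delimited long tables (one row per
frequency x level x trial), diffable and desk-scale; unit metadata and
provenance travel as JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "StimulusGrid",
    "ResponseGrid",
    "RateLevelFunction",
    "UnitRecord",
    "ConditionTriplet",
    "read_response_grid",
    "write_response_grid",
    "read_rlf",
    "write_rlf",
    "write_results",
    "read_results",
]


class ValidationError(ValueError):
    """Raised when data violate a structural invariant."""


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-D sequence")
    return arr


@dataclass(frozen=True)
class StimulusGrid:
    """Stimulus coordinates of an FRA or RLF measurement.

    Parameters
    ----------
    frequencies
        Tone frequencies in Hz, strictly increasing.
    levels
        Sound levels in dB attenuation, strictly increasing (larger = quieter).
    calibration
        Optional maximum system output in dB SPL; either a scalar (flat
        speaker response) or an array aligned with ``frequencies``.  Enables
        the SPL view ``spl = calibration - attenuation``.
    reference_frequency
        Optional estimated CF (Hz) anchoring the octave axis.
    """

    frequencies: np.ndarray
    levels: np.ndarray
    calibration: float | np.ndarray | None = None
    reference_frequency: float | None = None

    def __post_init__(self) -> None:
        freqs = _as_float_vector(self.frequencies, "frequencies")
        levels = _as_float_vector(self.levels, "levels")
        if np.any(np.diff(freqs) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        if np.any(np.diff(levels) <= 0):
            raise ValidationError("levels (dB attenuation) must be strictly increasing")
        if np.any(freqs <= 0):
            raise ValidationError("frequencies must be positive")
        calib = self.calibration
        if calib is not None and np.ndim(calib) == 1:
            calib = np.asarray(calib, dtype=float)
            if calib.shape != freqs.shape:
                raise ValidationError("per-frequency calibration must align with frequencies")
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "calibration", calib)

    @property
    def n_frequencies(self) -> int:
        return self.frequencies.size

    @property
    def n_levels(self) -> int:
        return self.levels.size

    def octaves(self, reference: float | None = None) -> np.ndarray:
        """Frequency axis in octaves re ``reference`` (default: the grid's
        reference frequency).  The octave coordinate is authoritative for
        spacing checks and for the tuning-curve fit."""
        ref = reference if reference is not None else self.reference_frequency
        if ref is None:
            raise ValidationError("no reference frequency available for octave axis")
        return np.log2(self.frequencies / ref)

    def spl(self) -> np.ndarray:
        """Level axis as dB SPL per (frequency, level); requires calibration."""
        if self.calibration is None:
            raise ValidationError("no calibration: SPL view unavailable")
        calib = np.broadcast_to(
            np.asarray(self.calibration, dtype=float), self.frequencies.shape
        )
        return calib[:, None] - self.levels[None, :]

    def __eq__(self, other) -> bool:  # value semantics for triplet checks
        if not isinstance(other, StimulusGrid):
            return NotImplemented
        return (
            np.array_equal(self.frequencies, other.frequencies)
            and np.array_equal(self.levels, other.levels)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class ResponseGrid:
    """Trial-wise spike counts on a frequency x level grid.

    ``counts`` has shape ``(n_frequencies, n_levels, n_trials)`` and holds
    non-negative integers (spikes per 75-ms presentation).
    """

    grid: StimulusGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValidationError("counts must be (n_frequencies, n_levels, n_trials)")
        if counts.shape[:2] != (self.grid.n_frequencies, self.grid.n_levels):
            raise ValidationError(
                f"counts shape {counts.shape[:2]} does not match grid "
                f"({self.grid.n_frequencies}, {self.grid.n_levels})"
            )
        if counts.shape[2] < 1:
            raise ValidationError("at least one trial per bin required")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise ValidationError("spike counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("spike counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[2]

    def mean_counts(self) -> np.ndarray:
        """Per-bin mean spike count across trials, shape (n_freq, n_levels)."""
        return self.counts.mean(axis=2)


@dataclass(frozen=True)
class RateLevelFunction:
    """Trial-wise spike counts at the CF across sound levels.

    ``counts`` has shape ``(n_levels, n_trials)``; levels are stored in dB
    attenuation, increasing (so the *loudest* stimulus is the first row).
    By convention RLFs are built from 20 or 50 repetitions per level;
    pass ``allowed_trials=None`` to lift the check.
    """

    frequency: float
    levels: np.ndarray
    counts: np.ndarray
    calibration: float | None = None
    allowed_trials: tuple[int, ...] | None = (20, 50)

    def __post_init__(self) -> None:
        levels = _as_float_vector(self.levels, "levels")
        if np.any(np.diff(levels) <= 0):
            raise ValidationError("levels (dB attenuation) must be strictly increasing")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != levels.size:
            raise ValidationError("counts must be (n_levels, n_trials)")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise ValidationError("spike counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("spike counts must be non-negative")
        if self.allowed_trials is not None and counts.shape[1] not in self.allowed_trials:
            raise ValidationError(
                f"trial count {counts.shape[1]} not in allowed set {self.allowed_trials}"
            )
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "counts", counts)

    @property
    def n_levels(self) -> int:
        return self.levels.size

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    def quiet_to_loud(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(levels, counts)`` ordered from quietest to loudest.

        The level axis is converted to dB SPL when a calibration is present
        (the reporting coordinate), otherwise left in dB attenuation; either
        way the arrays run from quiet to loud.
        """
        order = np.argsort(-self.levels)  # descending attenuation = quiet first
        levels = self.levels[order]
        if self.calibration is not None:
            levels = self.calibration - levels
        return levels, self.counts[order]

    @property
    def level_coordinate(self) -> str:
        return "spl" if self.calibration is not None else "attenuation"


@dataclass(frozen=True)
class UnitRecord:
    """Metadata of one recorded single unit."""

    unit_id: str
    estimated_cf: float
    fra_class: str = "V"  # {"V", "nonV"}
    subtype: str | None = None  # nonV only: low-tilt / narrow / closed / broad / ...
    deactivation_method: str = "cooling"  # {"cooling", "MDP"}

    def __post_init__(self) -> None:
        if self.fra_class not in ("V", "nonV"):
            raise ValidationError(f"fra_class must be 'V' or 'nonV', got {self.fra_class!r}")
        if self.fra_class == "V" and self.subtype is not None:
            raise ValidationError("subtype is only meaningful for nonV units")
        if self.deactivation_method not in ("cooling", "MDP"):
            raise ValidationError("deactivation_method must be 'cooling' or 'MDP'")


Measurement = ResponseGrid | RateLevelFunction


@dataclass(frozen=True)
class ConditionTriplet:
    """The {control, deactivated, recovery} measurements of one unit.

    Control is mandatory; all present measurements must share the same
    stimulus coordinates (each neuron serves as its own control).
    """

    control: Measurement
    deactivated: Measurement | None = None
    recovery: Measurement | None = None

    def __post_init__(self) -> None:
        if self.control is None:
            raise ValidationError("control measurement is required")
        for name, m in (("deactivated", self.deactivated), ("recovery", self.recovery)):
            if m is None:
                continue
            if type(m) is not type(self.control):
                raise ValidationError(f"{name} measurement type differs from control")
            if isinstance(m, ResponseGrid):
                if m.grid != self.control.grid:  # type: ignore[union-attr]
                    raise ValidationError(f"{name} stimulus grid differs from control")
            else:
                same = (
                    np.array_equal(m.levels, self.control.levels)  # type: ignore[union-attr]
                    and m.frequency == self.control.frequency  # type: ignore[union-attr]
                )
                if not same:
                    raise ValidationError(f"{name} stimulus levels differ from control")

    def conditions(self) -> dict[str, Measurement]:
        out: dict[str, Measurement] = {"control": self.control}
        if self.deactivated is not None:
            out["deactivated"] = self.deactivated
        if self.recovery is not None:
            out["recovery"] = self.recovery
        return out


# ---------------------------------------------------------------------------
# long-table text formats
# ---------------------------------------------------------------------------

_GRID_COLUMNS = ["frequency", "level", "trial", "count"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _read_long_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: one for the header, one for 1-based line numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValidationError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def read_response_grid(
    path: str | Path,
    *,
    calibration: float | None = None,
    reference_frequency: float | None = None,
) -> ResponseGrid:
    """Read a long-table FRA (columns frequency, level, trial, count).

    Every (frequency, level) cell must be present with the same number of
    trials; a missing cell is an error, never a silent zero.
    """
    df = _read_long_table(path, _GRID_COLUMNS)
    freqs = np.sort(df["frequency"].unique())
    levels = np.sort(df["level"].unique())
    trials = np.sort(df["trial"].unique())
    expected = freqs.size * levels.size * trials.size
    pivot = df.pivot_table(
        index="frequency", columns=["level", "trial"], values="count", aggfunc="sum"
    )
    if len(df) != expected or pivot.isna().any().any():
        per_cell = df.groupby(["frequency", "level"]).size()
        bad = per_cell[per_cell != trials.size]
        if len(bad):
            raise ValidationError(
                f"{path}: inconsistent trial counts; first offending cell "
                f"(frequency, level) = {bad.index[0]}"
            )
        full = pd.MultiIndex.from_product([freqs, levels])
        missing = full.difference(pd.MultiIndex.from_frame(df[["frequency", "level"]]))
        raise ValidationError(
            f"{path}: missing (frequency, level) cell(s), first = {tuple(missing[0])}"
        )
    counts = (
        df.sort_values(["frequency", "level", "trial"])["count"]
        .to_numpy()
        .reshape(freqs.size, levels.size, trials.size)
    )
    grid = StimulusGrid(freqs, levels, calibration=calibration,
                        reference_frequency=reference_frequency)
    return ResponseGrid(grid, counts)


def write_response_grid(rg: ResponseGrid, path: str | Path) -> Path:
    """Write a ResponseGrid as a delimited long table (round-trips bit-exactly)."""
    path = Path(path)
    f, l, t = np.meshgrid(
        rg.grid.frequencies, rg.grid.levels, np.arange(rg.n_trials), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "frequency": f.ravel(),
            "level": l.ravel(),
            "trial": t.ravel().astype(int),
            "count": rg.counts.ravel(),
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_rlf(
    path: str | Path,
    *,
    calibration: float | None = None,
    allowed_trials: tuple[int, ...] | None = (20, 50),
) -> RateLevelFunction:
    """Read a long-table RLF (columns frequency, level, trial, count)."""
    df = _read_long_table(path, _GRID_COLUMNS)
    freqs = df["frequency"].unique()
    if freqs.size != 1:
        raise ValidationError(f"{path}: an RLF must have a single frequency, found {freqs.size}")
    levels = np.sort(df["level"].unique())
    per_level = df.groupby("level").size()
    if per_level.nunique() != 1:
        raise ValidationError(f"{path}: unequal trial counts across levels")
    n_trials = int(per_level.iloc[0])
    counts = (
        df.sort_values(["level", "trial"])["count"].to_numpy().reshape(levels.size, n_trials)
    )
    return RateLevelFunction(
        float(freqs[0]), levels, counts, calibration=calibration, allowed_trials=allowed_trials
    )


def write_rlf(rlf: RateLevelFunction, path: str | Path) -> Path:
    path = Path(path)
    l, t = np.meshgrid(rlf.levels, np.arange(rlf.n_trials), indexing="ij")
    df = pd.DataFrame(
        {
            "frequency": rlf.frequency,
            "level": l.ravel(),
            "trial": t.ravel().astype(int),
            "count": rlf.counts.ravel(),
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


# ---------------------------------------------------------------------------
# results tables + provenance sidecar
# ---------------------------------------------------------------------------

def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(x).items()}
    if isinstance(x, Mapping):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_results(
    results: Iterable,
    path: str | Path,
    *,
    provenance: Mapping | None = None,
) -> Path:
    """Write a collection of result dataclasses as a TSV with a JSON sidecar.

    Field order follows the dataclass definition (deterministic); an empty
    collection yields a header-only table when the record type is given via
    ``results`` being an empty list of a known type -- otherwise just an empty
    file with no header.  The sidecar records provenance (e.g. config hash,
    seed) next to the schema.
    """
    path = Path(path)
    results = list(results)
    if results:
        first = results[0]
        if dataclasses.is_dataclass(first):
            fields = [f.name for f in dataclasses.fields(first)]
            rows = [
                {k: _jsonable(v) for k, v in dataclasses.asdict(r).items()} for r in results
            ]
            df = pd.DataFrame(rows, columns=fields)
            schema = {"record_type": type(first).__name__, "fields": fields}
        else:
            df = pd.DataFrame(results)
            schema = {"record_type": "mapping", "fields": list(df.columns)}
    else:
        df = pd.DataFrame()
        schema = {"record_type": None, "fields": []}
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"schema": schema, "provenance": _jsonable(dict(provenance or {}))}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
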