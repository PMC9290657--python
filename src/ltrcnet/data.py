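"""Core data structures, validation and delimited-file I/O for LTRC survival data.

A left-truncated, right-censored (LTRC) dataset records, for each subject,
an entry time ``v`` (delayed entry / left-truncation time), an observed
time ``y`` (event or censoring, measured from the same time origin as
``v``), an event indicator ``e`` and a predictor vector ``x``.  Subjects
appear in the data only if they survived past their entry time, so every
stored row satisfies ``y > v``.

Time units are caller-defined; the simulation layer documents years.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names with a fixed meaning in delimited files.
RESERVED_COLUMNS = ("entry", "time", "event")


class ValidationError(ValueError):
    """A table or array does not satisfy the LTRC data contract."""


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclasses.dataclass
class LTRCDataset:
    """Validated left-truncated right-censored survival data.

    Parameters
    ----------
    entry : (n,) array
        Nonnegative entry (left-truncation) times ``v``.
    time : (n,) array
        Observed event/censoring times ``y``; strictly greater than ``entry``.
    event : (n,) array
        Event indicators in {0, 1}; 1 means the event was observed.
    predictors : (n, p) array
        Real predictor matrix ``x``.
    predictor_names : sequence of str
        Length-p labels for the predictor columns.
    id : optional (n,) array
        Subject labels, free-form.
    """

    entry: np.ndarray
    time: np.ndarray
    event: np.ndarray
    predictors: np.ndarray
    predictor_names: Sequence[str]
    id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.entry = _as_float_vector(self.entry, "entry")
        self.time = _as_float_vector(self.time, "time")
        self.event = np.asarray(self.event, dtype=int)
        self.predictors = np.asarray(self.predictors, dtype=float)
        if self.predictors.ndim == 1:
            self.predictors = self.predictors.reshape(-1, 1)
        self.predictor_names = list(self.predictor_names)
        if self.id is not None:
            self.id = np.asarray(self.id)
        self._check()

    # -- invariants -----------------------------------------------------
    def _check(self) -> None:
        n = len(self.entry)
        for name, arr in (("time", self.time), ("event", self.event)):
            if len(arr) != n:
                raise ValidationError(f"{name} has length {len(arr)}, expected {n}")
        if self.predictors.shape[0] != n:
            raise ValidationError(
                f"predictors has {self.predictors.shape[0]} rows, expected {n}"
            )
        if len(self.predictor_names) != self.predictors.shape[1]:
            raise ValidationError(
                f"{len(self.predictor_names)} predictor names for "
                f"{self.predictors.shape[1]} predictor columns"
            )
        if self.id is not None and len(self.id) != n:
            raise ValidationError(f"id has length {len(self.id)}, expected {n}")
        for name, arr in (("entry", self.entry), ("time", self.time)):
            if not np.all(np.isfinite(arr)):
                bad = np.flatnonzero(~np.isfinite(arr))
                raise ValidationError(f"{name} contains non-finite values at rows {bad.tolist()[:10]}")
        if not np.all(np.isfinite(self.predictors)):
            bad = np.flatnonzero(~np.isfinite(self.predictors).all(axis=1))
            raise ValidationError(f"predictors contain non-finite values at rows {bad.tolist()[:10]}")
        if np.any(self.entry < 0):
            bad = np.flatnonzero(self.entry < 0)
            raise ValidationError(f"entry must be nonnegative; violated at rows {bad.tolist()[:10]}")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event must be 0/1")
        bad = np.flatnonzero(self.time <= self.entry)
        if bad.size:
            raise ValidationError(
                "time must be strictly greater than entry (subjects must survive "
                f"past entry); violated at rows {bad.tolist()[:10]}"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.entry)

    @property
    def p(self) -> int:
        return self.predictors.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "LTRCDataset":
        """Row subset as a new dataset (boolean mask or integer indices)."""
        idx = np.asarray(idx)
        return LTRCDataset(
            entry=self.entry[idx],
            time=self.time[idx],
            event=self.event[idx],
            predictors=self.predictors[idx],
            predictor_names=self.predictor_names,
            id=None if self.id is None else self.id[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"entry": self.entry, "time": self.time, "event": self.event})
        for j, name in enumerate(self.predictor_names):
            df[name] = self.predictors[:, j]
        if self.id is not None:
            df.insert(0, "id", self.id)
        return df


@dataclasses.dataclass
class CompleteCohort:
    """A fully simulated cohort including subjects lost to left truncation.

    Latent survival ``T``, censoring ``U`` and entry ``V`` times are all
    retained; the observable quantities are ``Y = min(T, U)`` and
    ``e = 1[T <= U]``.  A subject is truncated (never observed in a real
    study) when ``V > Y``.
    """

    latent_T: np.ndarray
    latent_U: np.ndarray
    latent_V: np.ndarray
    observed_Y: np.ndarray
    event: np.ndarray
    truncated: np.ndarray
    predictors: np.ndarray
    true_beta: np.ndarray
    predictor_names: Sequence[str]

    def __post_init__(self) -> None:
        self.latent_T = _as_float_vector(self.latent_T, "latent_T")
        self.latent_U = _as_float_vector(self.latent_U, "latent_U")
        self.latent_V = _as_float_vector(self.latent_V, "latent_V")
        self.observed_Y = _as_float_vector(self.observed_Y, "observed_Y")
        self.event = np.asarray(self.event, dtype=int)
        self.truncated = np.asarray(self.truncated, dtype=int)
        self.predictors = np.asarray(self.predictors, dtype=float)
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        self.predictor_names = list(self.predictor_names)
        if not np.array_equal(self.observed_Y, np.minimum(self.latent_T, self.latent_U)):
            raise ValidationError("observed_Y must equal min(latent_T, latent_U)")
        if not np.array_equal(self.event, (self.latent_T <= self.latent_U).astype(int)):
            raise ValidationError("event must equal 1[latent_T <= latent_U]")
        if not np.array_equal(self.truncated, (self.latent_V > self.observed_Y).astype(int)):
            raise ValidationError("truncated must equal 1[latent_V > observed_Y]")

    @property
    def n(self) -> int:
        return len(self.observed_Y)

    def observed(self, rows=None) -> LTRCDataset:
        """The non-truncated subset as a validated :class:`LTRCDataset`.

        ``rows`` optionally restricts to a subset of cohort rows (e.g. a
        train/test partition) before applying the truncation filter.
        """
        keep = self.truncated == 0
        if rows is not None:
            mask = np.zeros(self.n, dtype=bool)
            mask[np.asarray(rows)] = True
            keep = keep & mask
        return LTRCDataset(
            entry=self.latent_V[keep],
            time=self.observed_Y[keep],
            event=self.event[keep],
            predictors=self.predictors[keep],
            predictor_names=self.predictor_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "entry": self.latent_V,
                "time": self.observed_Y,
                "event": self.event,
                "latent_T": self.latent_T,
                "latent_U": self.latent_U,
                "latent_V": self.latent_V,
                "truncated": self.truncated,
            }
        )
        for j, name in enumerate(self.predictor_names):
            df[name] = self.predictors[:, j]
        return df


def validate_dataset(
    raw_table: pd.DataFrame,
    column_map: Mapping[str, object] | None = None,
    drop_invalid: bool = False,
) -> LTRCDataset:
    """Validate a columnar table into an :class:`LTRCDataset`.

    ``column_map`` may rename the roles, e.g. ``{"entry": "lt_time",
    "time": "os_years", "event": "death", "predictors": ["age", "tp53"]}``.
    Without a map, the reserved columns :data:`RESERVED_COLUMNS` are used and
    every other column is a predictor.

    Rows violating the row-level contract (missing values, negative entry,
    ``time <= entry``, non-binary event) raise :class:`ValidationError`
    naming the offending rows, unless ``drop_invalid`` is true, in which
    case they are dropped with a logged count.
    """
    cmap = dict(column_map or {})
    entry_col = cmap.get("entry", "entry")
    time_col = cmap.get("time", "time")
    event_col = cmap.get("event", "event")
    for role, col in (("entry", entry_col), ("time", time_col), ("event", event_col)):
        if col not in raw_table.columns:
            raise ValidationError(f"required column {col!r} (role {role!r}) not in table")
    pred_cols = cmap.get("predictors")
    if pred_cols is None:
        pred_cols = [c for c in raw_table.columns if c not in (entry_col, time_col, event_col, "id")]
    else:
        missing = [c for c in pred_cols if c not in raw_table.columns]
        if missing:
            raise ValidationError(f"column_map predictors not in table: {missing}")

    entry = pd.to_numeric(raw_table[entry_col], errors="coerce").to_numpy(dtype=float)
    time = pd.to_numeric(raw_table[time_col], errors="coerce").to_numpy(dtype=float)
    event_raw = pd.to_numeric(raw_table[event_col], errors="coerce").to_numpy(dtype=float)
    X = raw_table[pred_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if X.size == 0:
        X = X.reshape(len(raw_table), 0)

    bad = ~np.isfinite(entry) | ~np.isfinite(time) | ~np.isfinite(event_raw)
    if X.shape[1]:
        bad |= ~np.isfinite(X).all(axis=1)
    bad |= entry < 0
    bad |= time <= entry
    event_ok = np.isin(event_raw, (0.0, 1.0))
    if not event_ok.all() and not drop_invalid:
        raise ValidationError("event must be 0/1")
    bad |= ~event_ok

    if bad.any():
        if not drop_invalid:
            rows = np.flatnonzero(bad).tolist()
            raise ValidationError(
                f"{bad.sum()} invalid rows (missing values, negative entry, "
                f"time <= entry, or non-binary event) at rows {rows[:10]}"
            )
        logger.info("dropping %d invalid rows during validation", int(bad.sum()))
    keep = ~bad
    ids = raw_table["id"].to_numpy() if "id" in raw_table.columns else None
    return LTRCDataset(
        entry=entry[keep],
        time=time[keep],
        event=event_raw[keep].astype(int),
        predictors=X[keep],
        predictor_names=list(pred_cols),
        id=None if ids is None else ids[keep],
    )


def read_table(path, column_map: Mapping[str, object] | None = None) -> LTRCDataset:
    """Read a delimited text file (comma- or tab-separated, with header)."""
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    return validate_dataset(df, column_map=column_map)


def write_table(dataset: LTRCDataset, path) -> None:
    """Write a dataset as delimited text; ``.tsv`` extension selects tabs.

    Floats are written at full round-trip precision, so write → read is an
    identity.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def train_test_split(
    dataset: LTRCDataset, train_fraction: float, seed: int
) -> tuple[LTRCDataset, LTRCDataset]:
    """Disjoint random row partition; train size is ``round(fraction * n)``.

    The partition depends only on ``(n, train_fraction, seed)``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if dataset.n < 2:
        raise ValueError("need at least 2 rows to split")
    perm = np.random.default_rng(seed).permutation(dataset.n)
    n_train = int(round(train_fraction * dataset.n))
    return dataset.subset(np.sort(perm[:n_train])), dataset.subset(np.sort(perm[n_train:]))


def split_indices(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Index-level version of :func:`train_test_split` (same partition)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
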