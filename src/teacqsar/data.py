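"""Compound panel and descriptor-table handling.

Holds the measured drug panel (82 pharmaceuticals with TEAC activities),
the in-memory descriptor table used throughout the modeling pipeline,
min-max normalization learned on training compounds, removal of degenerate
descriptors ahead of variable selection, the three-band interpretation of
TEAC values, and the activity-ranked ("rational") train/test split.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "DescriptorTable",
    "NormalizationParams",
    "SplitAssignment",
    "load_table1",
    "classify_band",
    "band_counts",
    "filter_descriptors",
    "normalize",
    "rational_split",
    "BAND_LOW_UPPER",
    "BAND_HIGH_LOWER",
]

#: TEAC band cutoffs in mM.  The middle band is closed on both ends:
#: low < 0.100 <= mid <= 0.200 < high.
BAND_LOW_UPPER = 0.100
BAND_HIGH_LOWER = 0.200


@dataclass(frozen=True)
class CompoundRecord:
    """One drug of the measured panel with its TEAC activity in mM."""

    name: str
    cas: str
    molecular_formula: str
    pharmacologic_class: str
    atc: str
    teac: float

    def __post_init__(self) -> None:
        if self.teac < 0:
            raise ValueError(f"negative TEAC for {self.name}: {self.teac}")


@dataclass
class DescriptorTable:
    """Compounds x named-descriptor matrix with an optional activity vector.

    ``data`` is a DataFrame indexed by compound id with one column per
    descriptor; ``activity`` (TEAC, mM) shares the same index when present.
    """

    data: pd.DataFrame
    activity: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate compound ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate descriptor names")
        if self.activity is not None:
            self.activity = pd.Series(self.activity, index=self.data.index,
                                      dtype=float, name="activity")

    @property
    def compound_ids(self) -> list:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_compounds(self) -> int:
        return len(self.data)

    @property
    def n_descriptors(self) -> int:
        return self.data.shape[1]

    def subset_rows(self, ids) -> "DescriptorTable":
        act = self.activity.loc[ids] if self.activity is not None else None
        return DescriptorTable(self.data.loc[ids].copy(), act)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        if self.activity is not None:
            out["activity"] = self.activity
        out.to_csv(path, index_label="compound_id")

    @classmethod
    def from_csv(cls, path, activity_column: str | None = "activity") -> "DescriptorTable":
        frame = pd.read_csv(path, index_col=0)
        activity = None
        if activity_column is not None and activity_column in frame.columns:
            activity = frame.pop(activity_column)
        return cls(frame, activity)


def load_table1() -> list[CompoundRecord]:
    """Load the packaged 82-compound drug panel with measured TEAC values."""
    ref = importlib.resources.files("teacqsar.fixtures") / "table1_compounds.csv"
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(path)
    records = [
        CompoundRecord(
            name=row["name"],
            cas=str(row["cas"]),
            molecular_formula=row["molecular_formula"],
            pharmacologic_class=row["pharmacologic_class"],
            atc=row["atc"],
            teac=float(row["teac_mm"]),
        )
        for _, row in frame.iterrows()
    ]
    if len(records) != 82:
        raise RuntimeError(f"corrupted compound fixture: {len(records)} rows, expected 82")
    return records


def classify_band(teac: float) -> str:
    """Assign a TEAC value (mM) to the low / mid / high activity band.

    Low is strictly below 0.100 mM, high strictly above 0.200 mM, and the
    mid band 0.100-0.200 mM is closed on both ends.
    """
    if teac < 0:
        raise ValueError(f"negative TEAC: {teac}")
    if teac < BAND_LOW_UPPER:
        return "low"
    if teac <= BAND_HIGH_LOWER:
        return "mid"
    return "high"


def band_counts(teacs) -> dict[str, int]:
    """Count compounds per activity band."""
    counts = {"low": 0, "mid": 0, "high": 0}
    for t in teacs:
        counts[classify_band(float(t))] += 1
    return counts


def filter_descriptors(
    table: DescriptorTable,
    variance_tol: float = 0.0,
    pair_r_max: float = 0.95,
) -> tuple[DescriptorTable, list[dict]]:
    """Drop degenerate descriptors ahead of variable selection.

    Removes (near-)constant columns whose variance is <= ``variance_tol``,
    then scans pairs in column order and removes the later member of any
    pair with |Pearson r| >= ``pair_r_max``.  Returns the reduced table and
    a removal log with one entry per dropped column.
    """
    if table.n_descriptors == 0:
        raise ValueError("empty descriptor table")
    log: list[dict] = []
    values = table.data.to_numpy(dtype=float)
    names = table.descriptor_names

    variances = values.var(axis=0, ddof=0)
    keep_mask = variances > variance_tol
    for name, var in zip(names, variances):
        if var <= variance_tol:
            log.append({"descriptor": name, "reason": "low_variance", "value": float(var)})

    kept_idx = np.flatnonzero(keep_mask)
    if kept_idx.size:
        corr = np.corrcoef(values[:, kept_idx], rowvar=False)
        corr = np.atleast_2d(corr)
        alive = np.ones(kept_idx.size, dtype=bool)
        for j in range(kept_idx.size):
            if not alive[j]:
                continue
            for k in range(j + 1, kept_idx.size):
                if alive[k] and abs(corr[j, k]) >= pair_r_max:
                    alive[k] = False
                    log.append({
                        "descriptor": names[kept_idx[k]],
                        "reason": "high_pair_correlation",
                        "partner": names[kept_idx[j]],
                        "value": float(corr[j, k]),
                    })
        survivors = [names[i] for i, a in zip(kept_idx, alive) if a]
    else:
        survivors = []
    if not survivors:
        raise ValueError("all descriptors removed by filtering")
    reduced = DescriptorTable(table.data[survivors].copy(), table.activity)
    return reduced, log


@dataclass
class NormalizationParams:
    """Per-descriptor (min, max) learned from training compounds only."""

    minima: pd.Series
    maxima: pd.Series

    def __post_init__(self) -> None:
        if (self.maxima < self.minima).any():
            raise ValueError("max < min in normalization parameters")

    def to_json(self, path) -> None:
        payload = {
            name: [float(self.minima[name]), float(self.maxima[name])]
            for name in self.minima.index
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            payload = json.load(fh)
        names = list(payload)
        mins = pd.Series({n: payload[n][0] for n in names})
        maxs = pd.Series({n: payload[n][1] for n in names})
        return cls(mins, maxs)


def normalize(
    table: DescriptorTable,
    params: NormalizationParams | None = None,
    train_ids=None,
) -> tuple[DescriptorTable, NormalizationParams, pd.DataFrame]:
    """Min-max scale descriptors to [0, 1] using training-set extremes.

    When ``params`` is None they are learned from ``train_ids`` (all rows if
    ``train_ids`` is None).  Returns the scaled table, the parameters, and a
    boolean mask marking values that fall outside [0, 1] (possible for test
    compounds; they are kept, not clipped).
    """
    if params is None:
        rows = table.data if train_ids is None else table.data.loc[train_ids]
        params = NormalizationParams(rows.min(axis=0), rows.max(axis=0))
    span = params.maxima - params.minima
    degenerate = span[span == 0]
    if len(degenerate):
        raise ValueError(
            f"zero-range descriptors (filter first): {list(degenerate.index)}")
    scaled = (table.data[params.minima.index] - params.minima) / span
    out_of_range = (scaled < 0) | (scaled > 1)
    return DescriptorTable(scaled, table.activity), params, out_of_range


@dataclass
class SplitAssignment:
    """Disjoint train/test compound-id sets covering the whole panel."""

    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train/test overlap")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"train_ids": list(self.train_ids),
                       "test_ids": list(self.test_ids)}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitAssignment":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["train_ids"], payload["test_ids"])


def rational_split(activities: pd.Series, n_test: int, seed: int = 0) -> SplitAssignment:
    """Activity-ranked train/test split covering the whole activity range.

    Compounds are sorted by activity (exact ties broken by a seeded draw);
    the minimum and maximum go to training so prediction stays
    interpolative.  The remaining ranks are cut into ``n_test`` contiguous
    equal-width bins and the middle member of each bin becomes a test
    compound, which spreads the test set across the activity range.
    """
    activities = pd.Series(activities, dtype=float)
    n = len(activities)
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    if n_test > n // 3:
        raise ValueError(f"n_test={n_test} too large for n={n} (max {n // 3})")
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n)
    order = np.lexsort((tiebreak, activities.to_numpy()))
    sorted_ids = list(activities.index[order])

    middle = sorted_ids[1:-1]  # extremes excluded -> always train
    test: list = []
    for chunk in np.array_split(np.arange(len(middle)), n_test):
        pick = middle[chunk[len(chunk) // 2]]
        test.append(pick)
    train_ids = [cid for cid in activities.index if cid not in set(test)]
    return SplitAssignment(train_ids=train_ids, test_ids=test)
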