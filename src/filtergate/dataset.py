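"""Per-condition summary curves and the experiment dataset container.

One :class:`ConditionCurve` holds, for a fixed internal/external KCl pair,
the voltage grid with the effective open-channel current I_OF, the closing
rate k_OM and the opening rate k_MO, each with replicate standard
deviations.  A dataset is a list of such curves; it round-trips to a flat
CSV with the schema::

    series_id, c_in_mM, c_out_mM, V_mV, I_OF_pA, I_sd_pA,
    kOM_per_s, kOM_sd, kMO_per_s, kMO_sd, n_rep
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = ["ConditionCurve", "ExperimentDataset", "DatasetSchemaError", "SCHEMA_COLUMNS"]

SCHEMA_COLUMNS = [
    "series_id",
    "c_in_mM",
    "c_out_mM",
    "V_mV",
    "I_OF_pA",
    "I_sd_pA",
    "kOM_per_s",
    "kOM_sd",
    "kMO_per_s",
    "kMO_sd",
    "n_rep",
]


class DatasetSchemaError(ValueError):
    """A dataset file violates the CSV schema (message names row and column)."""


@dataclass
class ConditionCurve:
    series_id: str
    c_in: float  # mM
    c_out: float  # mM
    V: np.ndarray  # mV, strictly increasing
    I_OF: np.ndarray  # pA
    I_sd: np.ndarray
    k_OM: np.ndarray  # s^-1
    k_OM_sd: np.ndarray
    k_MO: np.ndarray
    k_MO_sd: np.ndarray
    n_rep: int = 1

    def __post_init__(self) -> None:
        arrays = [self.V, self.I_OF, self.I_sd, self.k_OM, self.k_OM_sd, self.k_MO, self.k_MO_sd]
        n = len(self.V)
        if any(len(a) != n for a in arrays):
            raise DatasetSchemaError(f"series {self.series_id}: column length mismatch")
        if np.any(np.diff(self.V) <= 0):
            raise DatasetSchemaError(f"series {self.series_id}: voltage grid not strictly increasing")
        if self.c_in <= 0 or self.c_out <= 0:
            raise DatasetSchemaError(f"series {self.series_id}: non-positive concentration")
        for name, arr in (("I_sd", self.I_sd), ("kOM_sd", self.k_OM_sd), ("kMO_sd", self.k_MO_sd)):
            if np.any(arr < 0):
                raise DatasetSchemaError(f"series {self.series_id}: negative {name}")
        for name, arr in (("kOM_per_s", self.k_OM), ("kMO_per_s", self.k_MO)):
            bad = np.nonzero(~(arr > 0) & ~np.isnan(arr))[0]
            if bad.size:
                raise DatasetSchemaError(
                    f"series {self.series_id}, row {bad[0]}: {name} = {arr[bad[0]]} "
                    "(rate constants must be positive where present)"
                )

    def shifted(self, dV: float) -> "ConditionCurve":
        """Curve with all voltages shifted by ``dV`` (drift correction)."""
        return replace(self, V=self.V + dV)


@dataclass
class ExperimentDataset:
    curves: list[ConditionCurve]

    def __post_init__(self) -> None:
        ids = [c.series_id for c in self.curves]
        if len(set(ids)) != len(ids):
            raise DatasetSchemaError("duplicate series_id in dataset")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    def series(self, series_id: str) -> ConditionCurve:
        for c in self.curves:
            if c.series_id == series_id:
                return c
        raise KeyError(series_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            for i in range(len(c.V)):
                rows.append(
                    (
                        c.series_id,
                        c.c_in,
                        c.c_out,
                        c.V[i],
                        c.I_OF[i],
                        c.I_sd[i],
                        c.k_OM[i],
                        c.k_OM_sd[i],
                        c.k_MO[i],
                        c.k_MO_sd[i],
                        c.n_rep,
                    )
                )
        return pd.DataFrame(rows, columns=SCHEMA_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExperimentDataset":
        missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetSchemaError(f"missing columns {missing}")
        numeric = [c for c in SCHEMA_COLUMNS if c not in ("series_id",)]
        for col in numeric:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() & df[col].notna()]
            if len(bad):
                raise DatasetSchemaError(f"row {bad[0]}, column {col}: not numeric")
            df = df.assign(**{col: vals})
        curves = []
        for sid, grp in df.groupby("series_id", sort=False):
            grp = grp.sort_values("V_mV")
            curves.append(
                ConditionCurve(
                    series_id=str(sid),
                    c_in=float(grp["c_in_mM"].iloc[0]),
                    c_out=float(grp["c_out_mM"].iloc[0]),
                    V=grp["V_mV"].to_numpy(float),
                    I_OF=grp["I_OF_pA"].to_numpy(float),
                    I_sd=grp["I_sd_pA"].to_numpy(float),
                    k_OM=grp["kOM_per_s"].to_numpy(float),
                    k_OM_sd=grp["kOM_sd"].to_numpy(float),
                    k_MO=grp["kMO_per_s"].to_numpy(float),
                    k_MO_sd=grp["kMO_sd"].to_numpy(float),
                    n_rep=int(grp["n_rep"].iloc[0]),
                )
            )
        return cls(curves)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | Path) -> "ExperimentDataset":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls.from_frame(pd.read_csv(path))
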