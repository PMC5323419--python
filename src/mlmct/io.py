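"""Long-format panel I/O, run configuration, and bias-report writing."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("mlmct")

__all__ = ["read_long_panel", "write_long_panel", "write_bias_report",
           "RunConfig", "PanelSchemaError"]

REQUIRED_COLUMNS = ("subject", "occasion", "y", "z", "c")


class PanelSchemaError(ValueError):
    """A long-format panel file violates the schema."""


def read_long_panel(path) -> pd.DataFrame:
    """Read and validate a long-format panel CSV.

    Requires columns subject, occasion, y, z, c; integer occasions, numeric
    values, no duplicated (subject, occasion), and equal spacing within each
    subject.  Subject order follows first appearance in the file.  Balance
    across subjects is not required.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"{path}: missing columns {missing}")
    for col in ("occasion", "y", "z", "c"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            rows = [i + 2 for i in bad[:5]]  # header is line 1
            raise PanelSchemaError(
                f"{path}: non-numeric values in column {col!r} at file rows {rows}"
            )
        df[col] = vals
    if not np.allclose(df["occasion"], df["occasion"].astype(int)):
        raise PanelSchemaError(f"{path}: occasion must be integer")
    df["occasion"] = df["occasion"].astype(int)
    dup = df.duplicated(subset=["subject", "occasion"])
    if dup.any():
        rows = [i + 2 for i in df.index[dup][:5].tolist()]
        raise PanelSchemaError(
            f"{path}: duplicated (subject, occasion) at file rows {rows}"
        )
    for sid, grp in df.groupby("subject", sort=False):
        occ = np.sort(grp["occasion"].to_numpy())
        d = np.diff(occ)
        if len(d) and not np.all(d == d[0]):
            raise PanelSchemaError(
                f"{path}: unequal occasion spacing for subject {sid!r}"
            )
    # stable subject ordering: first appearance
    order = {s: i for i, s in enumerate(pd.unique(df["subject"]))}
    df = df.sort_values(
        ["subject", "occasion"], key=lambda s: s.map(order) if s.name == "subject" else s
    ).reset_index(drop=True)
    return df


def write_long_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def write_bias_report(report, outdir) -> list:
    """Write a bias report as per-parameter TSV tables plus a long CSV.

    One TSV per parameter block with rows (N, L) and columns rho_bar x
    method; missing cells are written as 'NA' (with a warning).  Byte output
    is deterministic given the report.  Returns the list of files written.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    params = list(dict.fromkeys(report.long["parameter"]))
    for p in params:
        wide = report.parameter_table(p)
        if wide.isna().any().any():
            log.warning("bias table for %s contains missing cells (written as NA)", p)
        path = outdir / f"bias_{p}.tsv"
        flat = wide.copy()
        flat.columns = [f"rho{r:g}_{m}" for r, m in wide.columns]
        flat.to_csv(path, sep="\t", float_format="%.4f", na_rep="NA")
        written.append(path)
    long_path = outdir / "bias_long.csv"
    report.long.to_csv(long_path, index=False, float_format="%.6f", na_rep="NA")
    written.append(long_path)
    conv_path = outdir / "convergence.csv"
    report.convergence.to_csv(conv_path, index=False, float_format="%.6f")
    written.append(conv_path)
    return written


_SCHEMA = {
    "mode": str,
    "N": int,
    "L": int,
    "rho_bar": float,
    "grid": str,
    "reps": int,
    "seed": int,
    "methods": list,
    "p": int,
    "order_selection": str,
    "rescale": bool,
    "out": str,
    "data": str,
    "truth": dict,
}
_MODES = ("simulate", "fit", "transform", "bias-report")


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    mode: str
    N: int = 20
    L: int = 20
    rho_bar: float = 0.0
    grid: str = "single"
    reps: int = 500
    seed: int = 0
    methods: list = field(default_factory=lambda: ["ID", "AR1", "CT"])
    p: int = 1
    order_selection: str | None = None
    rescale: bool = False
    out: str = "."
    data: str | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        bad = set(self.methods) - {"ID", "AR1", "CT"}
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")
        if self.reps < 1 or self.N < 1 or self.L < 3:
            raise ValueError("reps and N must be >= 1, L >= 3")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
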