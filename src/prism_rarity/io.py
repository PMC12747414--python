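"""CSV/JSON readers and writers and the run configuration.

Survival CSV schema (comment lines start with ``#``): either
``n,assayed,functional`` (raw clone counts) or ``n,proportion``.
Reports are written as JSON with sorted keys so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import pandas as pd

from .exceptions import ValidationError
from .survival import SurvivalCurve

__all__ = ["load_survival_csv", "write_report", "load_report", "RunConfig"]


def load_survival_csv(path) -> SurvivalCurve:
    """Parse and validate a mutational-survival CSV.

    Malformed rows are reported with their (1-based, post-comment) row
    numbers.
    """
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parse error types
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    frame.columns = [c.strip().lower() for c in frame.columns]
    cols = set(frame.columns)
    problems = []
    if {"n", "assayed", "functional"} <= cols:
        for i, row in frame.iterrows():
            if row["assayed"] <= 0:
                problems.append(f"row {i + 1}: assayed must be positive")
            elif not 0 <= row["functional"] <= row["assayed"]:
                problems.append(
                    f"row {i + 1}: functional {row['functional']} outside "
                    f"[0, assayed={row['assayed']}]")
        if problems:
            raise ValidationError("; ".join(problems))
        curve = SurvivalCurve.from_counts(
            frame["n"].astype(int).tolist(),
            frame["functional"].astype(int).tolist(),
            frame["assayed"].astype(int).tolist())
    elif {"n", "proportion"} <= cols:
        for i, row in frame.iterrows():
            if not 0 <= row["proportion"] <= 1:
                problems.append(
                    f"row {i + 1}: proportion {row['proportion']} outside "
                    "[0, 1]")
        if problems:
            raise ValidationError("; ".join(problems))
        curve = SurvivalCurve(tuple(frame["n"].astype(int)),
                              tuple(frame["proportion"].astype(float)))
    else:
        raise ValidationError(
            f"{path}: expected columns n,assayed,functional or n,proportion; "
            f"found {sorted(cols)}")
    return curve


def write_report(bundle: Dict[str, Any], path) -> Path:
    """Write a report bundle as deterministic JSON (sorted keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_report(path) -> Dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


_POSITIVE = ("t_m", "p_min")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run, loadable from JSON.

    Paths are resolved relative to the config file's directory.
    """

    protein: str = ""
    L: int = 0
    specificity: str = "high"
    survival_csv: Optional[str] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    sigma_alpha: float = 0.0
    sigma_beta: float = 0.0
    ddg_csv: Optional[str] = None
    ddg_model: Optional[dict] = None
    ptol: Optional[float] = None
    n0: Optional[int] = None
    p_n0: Optional[float] = None
    p_min: float = 1e-40
    t_m: float = 1e38
    g_th: float = 0.5
    convention: str = "round"
    nb_rounding: str = "round"
    target_rounding: str = "floor"
    seed: int = 0
    out_dir: str = "."

    def validate(self, base: Optional[Path] = None) -> "RunConfig":
        if self.L < 1:
            raise ValidationError("config: L must be a positive integer")
        if self.specificity not in ("low", "high"):
            raise ValidationError("config: specificity must be low|high")
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be positive")
        if self.convention not in ("round", "floor"):
            raise ValidationError("config: convention must be round|floor")
        for attr in ("survival_csv", "ddg_csv"):
            rel = getattr(self, attr)
            if rel is not None:
                p = (base / rel) if base is not None else Path(rel)
                if not p.exists():
                    raise ValidationError(f"config: missing file {p}")
                setattr(self, attr, str(p))
        return self

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw).validate(base=path.parent)

    def to_json(self, path) -> Path:
        return write_report({k: getattr(self, k)
                             for k in self.__dataclass_fields__}, path)
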