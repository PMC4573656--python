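"""File formats and run reports.

Tree lists are CSV with header ``species,plot_id,dbh_cm,ht_m`` (UTF-8, '.'
decimal separator; ht_m may be empty).  Equation specs and all machine
outputs are JSON; covariance matrices serialize row-major with an explicit
dimension so a report is self-describing.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .equations import BiomassEquation, FitStats, TreeRecord
from .exceptions import InputError
from .recovery import RecoveredStats

__all__ = [
    "read_tree_csv",
    "write_tree_csv",
    "read_equation_spec",
    "write_equation_spec",
    "RunReport",
    "write_report",
    "read_report",
    "recovered_stats_to_dict",
    "recovered_stats_from_dict",
]

_TREE_COLUMNS = ["species", "plot_id", "dbh_cm", "ht_m"]
_EQ_KEYS = {"name", "form", "coefficients", "basis", "scale", "weight_rule",
            "recoverable", "fit"}


def read_tree_csv(path) -> list[TreeRecord]:
    """Read and validate a tree list; failing rows are reported by line number."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"species": str, "plot_id": str})
    missing = [c for c in ("species", "dbh_cm") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}; "
                         f"expected header {','.join(_TREE_COLUMNS)}")
    trees, bad = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            ht = row.get("ht_m")
            plot = row.get("plot_id")
            trees.append(TreeRecord(
                species=str(row["species"]),
                dbh_cm=float(row["dbh_cm"]),
                ht_m=None if ht is None or pd.isna(ht) else float(ht),
                plot_id=None if plot is None or pd.isna(plot) else str(plot)))
        except (InputError, ValueError, TypeError) as exc:
            bad.append(f"line {line}: {exc}")
    if bad:
        raise InputError(f"{path}: {len(bad)} invalid row(s):\n" + "\n".join(bad))
    return trees


def write_tree_csv(trees: list[TreeRecord], path) -> None:
    df = pd.DataFrame({
        "species": [t.species for t in trees],
        "plot_id": [t.plot_id or "" for t in trees],
        "dbh_cm": [t.dbh_cm for t in trees],
        "ht_m": [t.ht_m if t.ht_m is not None else "" for t in trees],
    })
    df.to_csv(path, index=False)


def _equation_to_dict(eq: BiomassEquation, fit: FitStats) -> dict:
    d = {"name": eq.name, "form": eq.form,
         "coefficients": list(eq.coefficients), "basis": list(eq.basis),
         "scale": eq.scale, "weight_rule": eq.weight_rule,
         "recoverable": eq.recoverable,
         "fit": {"n": fit.n, "r2": fit.r_squared}}
    if fit.residual_sd is not None:
        d["fit"]["sigma_e"] = fit.residual_sd
    if fit.coef_se is not None:
        d["fit"]["coef_se"] = list(fit.coef_se)
    if fit.r_squared_is_adjusted is not None:
        d["fit"]["r2_adjusted"] = fit.r_squared_is_adjusted
    return d


def write_equation_spec(eq: BiomassEquation, fit: FitStats, path) -> None:
    Path(path).write_text(json.dumps(_equation_to_dict(eq, fit), indent=2,
                                     sort_keys=True) + "\n")


def read_equation_spec(path) -> tuple[BiomassEquation, FitStats]:
    """Parse an equation spec JSON; unknown extra keys warn, bad schema raises."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: not valid JSON: {exc}") from exc
    extra = set(data) - _EQ_KEYS
    if extra:
        warnings.warn(f"{path}: ignoring unknown key(s) {sorted(extra)}", stacklevel=2)
    for key in ("name", "form", "coefficients", "fit"):
        if key not in data:
            raise InputError(f"{path}: missing required key {key!r}")
    fit = data["fit"]
    if "n" not in fit or "r2" not in fit:
        raise InputError(f"{path}: fit block must contain 'n' and 'r2'")
    eq = BiomassEquation(
        name=data["name"], form=data["form"],
        coefficients=tuple(data["coefficients"]),
        basis=tuple(data.get("basis", ())),
        scale=data.get("scale", "log" if data["form"] == "log-linear" else "identity"),
        weight_rule=data.get("weight_rule", "none"),
        recoverable=data.get("recoverable", True))
    stats = FitStats(n=int(fit["n"]), r_squared=float(fit["r2"]),
                     residual_sd=fit.get("sigma_e"),
                     coef_se=tuple(fit["coef_se"]) if "coef_se" in fit else None,
                     r_squared_is_adjusted=fit.get("r2_adjusted"))
    return eq, stats


def recovered_stats_to_dict(stats: RecoveredStats) -> dict:
    q = stats.cov.shape[0]
    return {"sigma2_resid": stats.sigma2_resid, "q": q,
            "cov_row_major": [float(v) for v in np.asarray(stats.cov).ravel()],
            "B": stats.B_used, "mc_error_det_pct": stats.mc_error_det_pct,
            "method": stats.method, "condition_number": stats.condition_number,
            "repair_count": stats.repair_count,
            "gamma_fallback_count": stats.gamma_fallback_count}


def recovered_stats_from_dict(d: dict) -> RecoveredStats:
    q = int(d["q"])
    cov = np.array(d["cov_row_major"], dtype=float).reshape(q, q)
    return RecoveredStats(sigma2_resid=float(d["sigma2_resid"]), cov=cov,
                          B_used=int(d["B"]),
                          mc_error_det_pct=float(d["mc_error_det_pct"]),
                          method=d["method"],
                          condition_number=float(d["condition_number"]),
                          repair_count=int(d.get("repair_count", 0)),
                          gamma_fallback_count=int(d.get("gamma_fallback_count", 0)))


@dataclass
class RunReport:
    """Self-describing record of one CLI run (inputs, seed, outputs, warnings)."""

    command: str
    config: dict
    seed: int | None = None
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = __version__


def digest_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_report(report: RunReport, path) -> None:
    """Deterministic JSON serialization (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(report.__dict__, indent=2, sort_keys=True,
                                     default=str) + "\n")


def read_report(path) -> RunReport:
    data = json.loads(Path(path).read_text())
    return RunReport(**data)
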