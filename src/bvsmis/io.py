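"""File formats and result serialization.

Two plain-CSV input formats:

* covariates — header row of covariate names, first column of subject ids, one row
  per subject; empty/NA genotype cells are imputed to 0 (homozygous for the major
  allele) before standardization, with the imputation count logged;
* visit panel — long format with columns ``subject_id, time, result`` (time in years,
  result 0/1), one row per visit.

Every output file starts with ``#``-prefixed header comments carrying the package
version, the seed and a hash of the run configuration, so results are reproducible
from their own provenance line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .likelihood import CovariateMatrix, SelfReportPanel
from .sampler import ChainSummary, inclusion_probabilities
from .study import StudyResult

logger = logging.getLogger("bvsmis")

__all__ = [
    "read_covariates",
    "read_panel",
    "write_covariates",
    "write_panel",
    "write_inclusion",
    "write_study_table",
    "write_truth_sidecar",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Short deterministic digest of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(seed, config: dict | None) -> str:
    h = config_hash(config or {})
    return f"# bvsmis v{__version__}\n# seed={seed}\n# config_hash={h}\n"


def read_covariates(path: str | Path, standardize: bool = True) -> CovariateMatrix:
    """Read a covariate CSV (first column subject id, remaining columns numeric).

    Missing cells are imputed to 0 — the major-allele homozygote under dosage
    coding — before standardization; the imputation count is logged.
    """
    frame = pd.read_csv(path, comment="#", dtype={0: str})
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected a subject-id column plus at least one covariate")
    ids = frame.iloc[:, 0].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject id(s): {sorted(set(dup))}")
    values = frame.iloc[:, 1:]
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        logger.warning("%s: imputed %d missing genotype cell(s) to 0", path, n_missing)
        values = values.fillna(0.0)
    try:
        numeric = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric covariate cell: {exc}") from exc
    mat = CovariateMatrix(numeric.to_numpy(), list(values.columns), list(ids))
    return mat.standardized() if standardize else mat


def read_panel(path: str | Path, subject_ids: Sequence[str] | None = None) -> list[SelfReportPanel]:
    """Read a long-format visit panel CSV with columns subject_id, time, result.

    When ``subject_ids`` is given (e.g. from the covariate file) the panels are
    returned in that order and every listed subject must appear in the file.
    """
    frame = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    required = {"subject_id", "time", "result"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}, got {list(frame.columns)}")
    if not set(frame["result"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: result column must be binary 0/1")
    if (frame["time"] <= 0).any():
        bad = frame.index[frame["time"] <= 0][0]
        raise ValueError(f"{path}: non-positive visit time at data row {bad}")
    dups = frame.duplicated(subset=["subject_id", "time"])
    if dups.any():
        row = frame[dups].iloc[0]
        raise ValueError(
            f"{path}: duplicate (subject, time) pair ({row['subject_id']}, {row['time']})"
        )
    grouped = {
        sid: grp.sort_values("time")
        for sid, grp in frame.groupby("subject_id", sort=False)
    }
    order = list(grouped) if subject_ids is None else list(subject_ids)
    panels = []
    for sid in order:
        if sid not in grouped:
            raise ValueError(
                f"{path}: subject {sid!r} from the covariate file has no rows in the panel "
                "file (a subject with no visits must still be listed explicitly elsewhere)"
            )
        grp = grouped[sid]
        panels.append(
            SelfReportPanel(sid, grp["time"].to_numpy(float), grp["result"].to_numpy(np.int64))
        )
    return panels


def write_panel(panels: Sequence[SelfReportPanel], path: str | Path, seed=None, config=None) -> None:
    rows = [
        {"subject_id": p.subject_id, "time": t, "result": int(r)}
        for p in panels
        for t, r in zip(p.times, p.results)
    ]
    _write_frame(pd.DataFrame(rows, columns=["subject_id", "time", "result"]), path, seed, config)


def write_covariates(Z: CovariateMatrix, path: str | Path, seed=None, config=None) -> None:
    frame = pd.DataFrame(Z.values, columns=Z.names)
    frame.insert(0, "subject_id", Z.subject_ids)
    _write_frame(frame, path, seed, config)


def write_truth_sidecar(dataset, path: str | Path, seed=None) -> None:
    """Record the generative truth of a simulated dataset (true indices, X, design)."""
    d = dataset.design
    payload = {
        "true_idx": dataset.true_idx.tolist(),
        "true_names": [dataset.Z.names[i] for i in dataset.true_idx],
        "event_times": np.asarray(dataset.event_times).tolist(),
        "design": {
            "n": d.n,
            "P": d.P,
            "n_true": d.n_true,
            "beta_true": d.beta_true,
            "cir": d.cir,
            "duration": d.duration,
            "schedule": list(d.schedule),
            "sensitivity": d.accuracy.sensitivity,
            "specificity": d.accuracy.specificity,
            "design": d.design,
            "covariate_kind": d.covariate_kind,
        },
        "seed": seed,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _write_frame(frame: pd.DataFrame, path: str | Path, seed, config) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config))
        frame.to_csv(fh, index=False)


def write_inclusion(summary: ChainSummary, path: str | Path, config: dict | None = None) -> None:
    """Inclusion-probability CSV: covariate, probability, rank (best-first)."""
    probs, order = inclusion_probabilities(summary)
    rank = np.empty_like(order)
    rank[order] = np.arange(1, order.size + 1)
    names = summary.names or [f"V{p + 1}" for p in range(probs.size)]
    frame = pd.DataFrame({"covariate": names, "probability": probs, "rank": rank})
    _write_frame(frame, path, summary.seed, config)


def write_trace(summary: ChainSummary, path: str | Path, config: dict | None = None) -> None:
    if summary.trace is None:
        raise ValueError("chain was run without keep_trace=True")
    _write_frame(pd.DataFrame(summary.trace), path, summary.seed, config)


def write_study_table(result: StudyResult, path: str | Path, config: dict | None = None) -> None:
    """One row per (setting, strategy) with metric, SE, replicate count and seed."""
    _write_frame(result.to_frame(), path, result.config.seed, config)
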