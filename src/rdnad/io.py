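"""Readers and writers for the delimited-text formats the tool consumes.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimals; AD profiles are tab-separated with a small comment header.  Rows
with missing or unparseable descriptor values are dropped (never imputed) and
counted in the log.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import ADProfile, LabeledDescriptorSet, ProfileIteration
from .reliability import EnsemblePredictionMatrix

logger = logging.getLogger("rdnad.io")

__all__ = [
    "read_descriptor_table",
    "write_descriptor_table",
    "read_prediction_table",
    "write_prediction_table",
    "read_profile",
    "write_profile",
    "load_yaml_config",
    "setup_logging",
]

_PROFILE_COLUMNS = ["iteration", "threshold_param", "dataset", "n_included_cum", "accuracy_cum"]


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the requested level."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )


def read_descriptor_table(
    path: str | Path,
    id_col: str = "id",
    class_col: str = "observed",
    correct_col: str | None = None,
) -> LabeledDescriptorSet:
    """Read a compounds x descriptors CSV into a :class:`LabeledDescriptorSet`.

    Every column other than ``id_col``, ``class_col`` and ``correct_col`` is
    treated as a numeric descriptor.  Rows with missing or unparseable
    descriptor values are excluded and reported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in [id_col, class_col] + ([correct_col] if correct_col else []):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    meta_cols = {id_col, class_col} | ({correct_col} if correct_col else set())
    feature_names = [c for c in df.columns if c not in meta_cols]
    if not feature_names:
        raise ValueError(f"no descriptor columns found in {path}")

    X = df[feature_names].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    usable = np.isfinite(X).all(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "%s: excluded %d row(s) with missing/unparseable descriptor values (ids: %s)",
            path.name, n_dropped, df.loc[~usable, id_col].tolist(),
        )
    df = df.loc[usable]
    X = X[usable]
    if len(df) == 0:
        raise ValueError(f"{path}: zero usable rows after filtering")

    y = pd.to_numeric(df[class_col], errors="raise").to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{path}: class column {class_col!r} must be binary 0/1")
    correct = None
    if correct_col:
        correct = df[correct_col].astype(bool).to_numpy()
    return LabeledDescriptorSet(
        ids=df[id_col].astype(str).tolist(),
        X=X,
        feature_names=feature_names,
        y_observed=y.astype(int),
        correct=correct,
    )


def write_descriptor_table(
    dataset: LabeledDescriptorSet,
    path: str | Path,
    id_col: str = "id",
    class_col: str = "observed",
    correct_col: str = "correct",
) -> None:
    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    df.insert(0, class_col, dataset.y_observed)
    df.insert(0, id_col, dataset.ids)
    if dataset.correct is not None:
        df[correct_col] = dataset.correct.astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_prediction_table(path: str | Path) -> EnsemblePredictionMatrix:
    """Read a per-compound ensemble prediction CSV.

    Expected columns: ``id``, ``observed``, member columns ``m1..mM`` and/or
    ``mean_prob``, plus optional ``yhat_model`` and ``std``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("id", "observed"):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    member_cols = sorted(
        (c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    members = df[member_cols].to_numpy(dtype=float) if member_cols else None
    return EnsemblePredictionMatrix(
        ids=df["id"].astype(str).tolist(),
        members=members,
        y_observed=df["observed"].to_numpy(),
        yhat_model=df["yhat_model"].to_numpy() if "yhat_model" in df.columns else None,
        mean_prob=df["mean_prob"].to_numpy(dtype=float) if "mean_prob" in df.columns else None,
        std=df["std"].to_numpy(dtype=float) if "std" in df.columns else None,
    )


def write_prediction_table(epm: EnsemblePredictionMatrix, path: str | Path) -> None:
    df = pd.DataFrame({"id": epm.ids, "observed": epm.y_observed})
    if epm.yhat_model is not None:
        df["yhat_model"] = epm.yhat_model
    if epm.members is not None:
        for m in range(epm.n_members):
            df[f"m{m + 1}"] = epm.members[:, m]
    df["mean_prob"] = epm.mean_prob
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_profile(profile: ADProfile, path: str | Path) -> None:
    """Write an AD profile as TSV (one row per iteration x dataset)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for it in profile.iterations:
        for ds in profile.datasets:
            acc = it.accuracy[ds]
            rows.append((it.index, it.threshold, ds, it.n_included[ds],
                         "NA" if acc is None else repr(float(acc))))
    sizes = "\t".join(f"{d}={n}" for d, n in profile.dataset_sizes.items())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ad-profile\tmethod={profile.method}\n")
        fh.write(f"# dataset_sizes\t{sizes}\n")
        fh.write("\t".join(_PROFILE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_profile(path: str | Path) -> ADProfile:
    """Read a profile TSV, validating the profile invariants on the way in."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    method = "unknown"
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "ad-profile":
                for p in parts[1:]:
                    if p.startswith("method="):
                        method = p.split("=", 1)[1]
            elif parts[0] == "dataset_sizes":
                for p in parts[1:]:
                    d, n = p.split("=")
                    sizes[d] = int(n)
        else:
            body_start = i
            break
    header = lines[body_start].rstrip("\n").split("\t")
    if header != _PROFILE_COLUMNS:
        raise ValueError(f"{path}: malformed profile header {header}")
    table: dict[int, ProfileIteration] = {}
    for line in lines[body_start + 1:]:
        if not line.strip():
            continue
        idx_s, thr_s, ds, n_s, acc_s = line.rstrip("\n").split("\t")
        idx = int(idx_s)
        it = table.setdefault(idx, ProfileIteration(idx, float(thr_s), {}, {}))
        it.n_included[ds] = int(n_s)
        it.accuracy[ds] = None if acc_s == "NA" else float(acc_s)
    if not table:
        raise ValueError(f"{path}: empty profile")
    iterations = [table[i] for i in sorted(table)]
    if not sizes:
        sizes = {d: max(it.n_included[d] for it in iterations)
                 for d in iterations[0].n_included}
    return ADProfile(method=method, iterations=iterations, dataset_sizes=sizes)


def load_yaml_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
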