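"""Study container, multi-source input validation, and fit serialization.

Inputs come from three delimited-text sources -- a long-format longitudinal
table, a cross-sectional covariate table, and a subjects x features omics
matrix -- plus a GMT file mapping features to pathways.  ``assemble_study``
inner-joins them on subject id into a validated :class:`LongStudy`.
Missing-data policy is complete-case at the subject level; subjects dropped
at any stage are counted and logged.  Subject order is canonicalized to
sorted ids so seeded downstream runs are reproducible across input orderings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FIT_FORMAT_VERSION = 1


@dataclass
class LongStudy:
    """Aligned longitudinal + omics study data.

    Attributes
    ----------
    subject_ids : (n,) sorted unique identifiers.
    times, outcomes : per-subject arrays of visit times t_ij and outcomes
        y_i(t_ij), each of length T_i >= 1, times ascending.
    static_covs : (n, P+1) static covariates with intercept column prepended.
    long_covs : per-subject (T_i, M) longitudinal covariates v_im(t_ij).
    omics : (n, Q+1) omics features with intercept column prepended.
    feature_names : the Q omics feature names (order matches omics columns 1..Q).
    pathway_groups : dict pathway name -> array of 0-based feature indices;
        groups may overlap, features in no group form the ungrouped remainder.
    time_range : (t_min, t_max) over all observed visits.
    meta : free-form provenance (standardization, time rescaling, drop counts).
    """

    subject_ids: np.ndarray
    times: list
    outcomes: list
    static_covs: np.ndarray
    long_covs: list
    omics: np.ndarray
    feature_names: list
    pathway_groups: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def P(self) -> int:
        """Number of static covariates excluding the intercept."""
        return self.static_covs.shape[1] - 1

    @property
    def M(self) -> int:
        return self.long_covs[0].shape[1] if self.long_covs else 0

    @property
    def Q(self) -> int:
        return self.omics.shape[1] - 1

    @property
    def time_range(self) -> tuple[float, float]:
        t_all = np.concatenate(self.times)
        return float(t_all.min()), float(t_all.max())

    def subset(self, idx: np.ndarray) -> "LongStudy":
        """Row-subset by subject positions (used by cross-validation folds)."""
        idx = np.asarray(idx, dtype=int)
        return LongStudy(
            subject_ids=self.subject_ids[idx],
            times=[self.times[i] for i in idx],
            outcomes=[self.outcomes[i] for i in idx],
            static_covs=self.static_covs[idx],
            long_covs=[self.long_covs[i] for i in idx],
            omics=self.omics[idx],
            feature_names=self.feature_names,
            pathway_groups=self.pathway_groups,
            meta=dict(self.meta),
        )

    def restrict_features(self, keep: np.ndarray) -> "LongStudy":
        """Keep only the omics features at 0-based indices ``keep``."""
        keep = np.asarray(keep, dtype=int)
        cols = np.concatenate([[0], keep + 1])
        names = [self.feature_names[j] for j in keep]
        pos = {int(j): r for r, j in enumerate(keep)}
        groups = {}
        for name, g in self.pathway_groups.items():
            g2 = np.array([pos[int(j)] for j in g if int(j) in pos], dtype=int)
            if g2.size:
                groups[name] = g2
        return LongStudy(
            subject_ids=self.subject_ids,
            times=self.times,
            outcomes=self.outcomes,
            static_covs=self.static_covs,
            long_covs=self.long_covs,
            omics=self.omics[:, cols],
            feature_names=names,
            pathway_groups=groups,
            meta=dict(self.meta),
        )


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


def _read_table(path: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_long_table(
    path: str,
    id_col: str = "id",
    time_col: str = "time",
    outcome_col: str = "y",
    covariate_cols: list | None = None,
) -> dict:
    """Read the long-format longitudinal table into per-subject records.

    Returns a dict id -> {"times", "outcomes", "long_covs"} with visits sorted
    ascending by time within subject.  Duplicate (id, time) rows are rejected.
    """
    df = _read_table(path)
    covariate_cols = covariate_cols or []
    missing = [c for c in [id_col, time_col, outcome_col, *covariate_cols] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    for c in [time_col, outcome_col, *covariate_cols]:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {c!r} at row index {int(np.flatnonzero(bad)[0])}"
            )
        df[c] = coerced
    dup = df.duplicated(subset=[id_col, time_col])
    if dup.any():
        r = df.loc[dup.idxmax()]
        raise ValueError(f"duplicated (id, time) pair: ({r[id_col]!r}, {r[time_col]!r})")
    records = {}
    for sid, grp in df.groupby(id_col, sort=True):
        grp = grp.sort_values(time_col)
        records[sid] = {
            "times": grp[time_col].to_numpy(dtype=float),
            "outcomes": grp[outcome_col].to_numpy(dtype=float),
            "long_covs": grp[covariate_cols].to_numpy(dtype=float)
            if covariate_cols
            else np.zeros((len(grp), 0)),
        }
    return records


def read_static_table(path: str, id_col: str = "id", covariate_cols: list | None = None) -> pd.DataFrame:
    """Read the cross-sectional covariate table, indexed by subject id."""
    df = _read_table(path)
    if id_col not in df.columns:
        raise SchemaError(f"missing id column {id_col!r} in {path}")
    if covariate_cols is not None:
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"missing covariate column(s) {missing} in {path}")
        df = df[[id_col, *covariate_cols]]
    return df.set_index(id_col)


def read_omics_matrix(path: str) -> pd.DataFrame:
    """Read the subjects x features omics matrix (first column = subject id)."""
    df = _read_table(path)
    return df.set_index(df.columns[0])


def read_gmt(path: str, feature_names: list) -> dict:
    """Parse a GMT pathway file into named 0-based feature index sets.

    Each line: name <tab> description <tab> member names.  Members absent from
    ``feature_names`` are logged and skipped; a set with no known member is
    dropped with a warning.  Overlapping sets are permitted.
    """
    name_to_idx = {name: j for j, name in enumerate(feature_names)}
    groups: dict = {}
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("GMT set %r has no members; dropped", parts[0])
                continue
            set_name, members = parts[0], parts[2:]
            idx, unknown = [], []
            for m in members:
                if m in name_to_idx:
                    idx.append(name_to_idx[m])
                else:
                    unknown.append(m)
            if unknown:
                logger.warning(
                    "GMT set %r: %d unknown member(s) skipped (e.g. %r)",
                    set_name, len(unknown), unknown[0],
                )
            if not idx:
                logger.warning("GMT set %r has no known members; set dropped", set_name)
                continue
            groups[set_name] = np.array(sorted(set(idx)), dtype=int)
    if n_lines == 0:
        raise ValueError(f"empty GMT file: {path}")
    return groups


def assemble_study(
    long_records: dict,
    static_table: pd.DataFrame,
    omics_matrix: pd.DataFrame,
    pathway_groups: dict | None = None,
    standardize_omics: bool = True,
    rescale_time: bool = False,
) -> LongStudy:
    """Inner-join the three sources on subject id into a validated LongStudy.

    Subjects missing from any source, or carrying NaN in any required field,
    are dropped with a logged count.  Intercept columns are prepended to the
    static and omics blocks.  With ``standardize_omics`` each feature is
    centered and scaled to unit variance (constant features map to all-zeros
    with a warning).  With ``rescale_time`` visit times are affinely mapped to
    [0, 1]; the affine map is recorded in ``meta``.
    """
    ids_long = set(long_records)
    ids = sorted(ids_long & set(static_table.index) & set(omics_matrix.index))
    if not ids:
        raise ValueError("empty subject-id intersection across sources")
    n_union = len(ids_long | set(static_table.index) | set(omics_matrix.index))
    dropped_join = n_union - len(ids)

    keep, times, outcomes, long_covs = [], [], [], []
    for sid in ids:
        rec = long_records[sid]
        ok = (
            len(rec["times"]) >= 1
            and np.all(np.isfinite(rec["times"]))
            and np.all(np.isfinite(rec["outcomes"]))
            and np.all(np.isfinite(rec["long_covs"]))
            and np.all(np.isfinite(static_table.loc[sid].to_numpy(dtype=float)))
            and np.all(np.isfinite(omics_matrix.loc[sid].to_numpy(dtype=float)))
        )
        if ok:
            keep.append(sid)
        else:
            logger.info("subject %r dropped: missing data", sid)
    dropped_nan = len(ids) - len(keep)
    if dropped_join or dropped_nan:
        logger.info(
            "assemble_study: %d subject(s) dropped at join, %d with missing data; n=%d retained",
            dropped_join, dropped_nan, len(keep),
        )
    if not keep:
        raise ValueError("no complete-case subjects remain")

    for sid in keep:
        rec = long_records[sid]
        times.append(np.asarray(rec["times"], dtype=float))
        outcomes.append(np.asarray(rec["outcomes"], dtype=float))
        long_covs.append(np.asarray(rec["long_covs"], dtype=float))

    meta: dict = {"dropped_join": dropped_join, "dropped_missing": dropped_nan}
    if rescale_time:
        t_all = np.concatenate(times)
        lo, hi = float(t_all.min()), float(t_all.max())
        scale = hi - lo if hi > lo else 1.0
        times = [(t - lo) / scale for t in times]
        meta["time_rescale"] = {"offset": lo, "scale": scale}

    x = static_table.loc[keep].to_numpy(dtype=float)
    static_covs = np.hstack([np.ones((len(keep), 1)), x])

    g = omics_matrix.loc[keep].to_numpy(dtype=float)
    feature_names = list(omics_matrix.columns)
    if standardize_omics:
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        const = sd == 0
        if const.any():
            logger.warning(
                "%d constant omics feature(s) mapped to all-zeros under standardization",
                int(const.sum()),
            )
        sd_safe = np.where(const, 1.0, sd)
        g = (g - mu) / sd_safe
        g[:, const] = 0.0
        meta["omics_standardized"] = True
    omics = np.hstack([np.ones((len(keep), 1)), g])

    return LongStudy(
        subject_ids=np.asarray(keep),
        times=times,
        outcomes=outcomes,
        static_covs=static_covs,
        long_covs=long_covs,
        omics=omics,
        feature_names=feature_names,
        pathway_groups=dict(pathway_groups or {}),
        meta=meta,
    )


@dataclass
class FitConfig:
    """Fit configuration: subtype count, spline settings, penalties, EM control.

    Penalty fields hold single values; grids for tuning live in the tuning
    module.  ``nb >= degree + 1`` and all penalty weights must be nonnegative.
    """

    K: int = 3
    spline_degree: int = 3
    spline_nb: int = 8
    knot_rule: str = "equal"
    lambda1: float = 0.0
    lambda2: float = 0.0
    nu: float = 1.0
    kappa: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    n_restarts: int = 5
    seed: int | None = 0
    cv_folds: int = 5
    bootstrap_B: int = 200
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.spline_nb < self.spline_degree + 1:
            raise ValueError("nb must be >= degree + 1")
        for name in ("lambda1", "lambda2", "nu", "kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str) -> "FitConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def replace(self, **kw) -> "FitConfig":
        d = self.to_dict()
        d.update(kw)
        return FitConfig.from_dict(d)


# ---------------------------------------------------------------------------
# fit serialization
# ---------------------------------------------------------------------------


def write_fit(path: str, fit, config=None) -> None:
    """Serialize a fitted model to a single JSON document.

    Stores the full parameter set, the spline basis definition, the selected
    feature set, convergence diagnostics, seed and (optionally) the fit
    configuration, at full float precision.
    """
    doc = {
        "format_version": FIT_FORMAT_VERSION,
        "gamma": fit.params.gamma.tolist(),
        "theta": fit.params.theta.tolist(),
        "xi": fit.params.xi.tolist(),
        "sigma_eps": fit.params.sigma_eps.tolist(),
        "sigma_alpha": fit.params.sigma_alpha.tolist(),
        "basis": fit.basis.to_dict(),
        "selected_features": sorted(int(j) for j in fit.selected_features),
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "seed": None if fit.seed is None else int(fit.seed),
        "trace": [float(v) for v in fit.trace],
        "config": config if config is None or isinstance(config, dict) else config.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_fit(path: str):
    """Load a fit written by :func:`write_fit`; round-trips all parameters."""
    from .em_fit import FitResult  # deferred: em_fit imports this module
    from .model_core import ModelParams
    from .splines import SplineBasis

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt or truncated fit file {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != FIT_FORMAT_VERSION:
        raise ValueError(
            f"fit format version mismatch: file has {version!r}, expected {FIT_FORMAT_VERSION}"
        )
    params = ModelParams(
        gamma=np.asarray(doc["gamma"], dtype=float),
        theta=np.asarray(doc["theta"], dtype=float),
        xi=np.asarray(doc["xi"], dtype=float),
        sigma_eps=np.asarray(doc["sigma_eps"], dtype=float),
        sigma_alpha=np.asarray(doc["sigma_alpha"], dtype=float),
    )
    return FitResult(
        params=params,
        e_state=None,
        trace=list(doc["trace"]),
        converged=doc["converged"],
        n_iter=doc["n_iter"],
        seed=doc["seed"],
        selected_features=np.asarray(doc["selected_features"], dtype=int),
        basis=SplineBasis.from_dict(doc["basis"]),
        config=doc.get("config"),
    )
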