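"""Reduce tract bundles to per-subject mean FA and build the cohort table.

The tract summary statistic is the mean FA over all stepping points of all
fibers in a bundle ("pooled points", the default) or the mean of per-fiber
means; the pooled variant weights every sampled point equally, which matches
sampling FA at fixed arc steps along each fiber.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tracking import TractBundle

__all__ = ["mean_tract_fa", "build_cohort_table", "COVARIATE_COLUMNS"]

logger = logging.getLogger(__name__)

# fixed leading columns of a cohort table, in order
COVARIATE_COLUMNS = ["subject_id", "group", "age", "gender",
                     "duration_illness", "n_episodes"]

VALID_GROUPS = frozenset({"HC", "MDD", "BD"})


def mean_tract_fa(bundle: TractBundle, method: str = "pooled") -> float:
    """Mean FA of a tract bundle.

    method="pooled" (default): all per-point FA samples of all streamlines
    pooled and averaged, each stepping point weighted equally.
    method="per-fiber": mean of per-streamline mean FA values.

    An empty bundle yields NaN with a logged warning (a missing value, not
    an error: downstream statistics drop it pairwise).
    """
    if method not in ("pooled", "per-fiber"):
        raise ValueError(f"unknown method {method!r}; use 'pooled' or 'per-fiber'")
    if len(bundle) == 0:
        logger.warning("empty bundle for parcel %s (%s); mean FA is missing",
                       bundle.parcel_id, bundle.name or "unnamed")
        return float("nan")
    if method == "pooled":
        return float(np.concatenate([s.fa for s in bundle.streamlines]).mean())
    return float(np.mean([s.fa.mean() for s in bundle.streamlines]))


def build_cohort_table(bundles_by_subject: dict, covariates: pd.DataFrame,
                       tracts: list | tuple | None = None,
                       method: str = "pooled") -> pd.DataFrame:
    """Assemble the subjects x (covariates, tract mean FA) analysis table.

    Parameters
    ----------
    bundles_by_subject : dict
        ``{subject_id: {tract_name: TractBundle}}``.  An empty bundle (or an
        absent tract) becomes a missing value; the row is retained.
    covariates : DataFrame
        One row per subject with at least the columns in
        :data:`COVARIATE_COLUMNS` (cognition-score columns pass through).
    tracts : sequence of str, optional
        Column order for the FA block; defaults to the sorted union of
        tract names seen in ``bundles_by_subject``.

    The HC zero-fill convention is enforced: illness duration and episode
    count are set to 0 for every HC row (those variables are undefined for
    healthy controls and enter the group models as zeros).

    Raises
    ------
    ValueError
        If a subject with imaging data has no covariate row.
    """
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing_cols:
        raise ValueError(f"covariate table lacks required columns: {missing_cols}")
    bad_groups = set(covariates["group"]) - VALID_GROUPS
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}; expected {sorted(VALID_GROUPS)}")
    if covariates["subject_id"].duplicated().any():
        dups = covariates.loc[covariates["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in covariate table: {dups}")

    known = set(covariates["subject_id"])
    orphans = [s for s in bundles_by_subject if s not in known]
    if orphans:
        raise ValueError(f"covariates missing for subjects: {orphans}")

    if tracts is None:
        tracts = sorted({t for per_subj in bundles_by_subject.values() for t in per_subj})

    table = covariates.copy().reset_index(drop=True)
    hc = table["group"] == "HC"
    table.loc[hc, ["duration_illness", "n_episodes"]] = 0.0

    fa = pd.DataFrame(np.nan, index=table.index, columns=list(tracts))
    pos = {s: i for i, s in enumerate(table["subject_id"])}
    for subject, per_tract in bundles_by_subject.items():
        for tract, bundle in per_tract.items():
            if tract in fa.columns:
                fa.iloc[pos[subject], fa.columns.get_loc(tract)] = mean_tract_fa(bundle, method)
    return pd.concat([table, fa], axis=1)
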