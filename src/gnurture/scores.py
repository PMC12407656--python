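"""Transmitted and non-transmitted polygenic scores.

Per offspring, four haplotype scores are computed from the inferred
transmission map: maternal/paternal x transmitted/non-transmitted.  The
combined PGS_T (mT + pT) reconstructs the score of the offspring's own
genome; the combined PGS_NT (mNT + pNT) is the genetic-nurture exposure.  In
pair families the missing parent's non-transmitted score is missing and can
be mean-imputed (role-specific mean by default).  Scores are standardized by
z-scoring within genotyping batch after residualizing on the leading genetic
principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simfam import GeneticMap
from .transmission import TransmissionMap

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedWeights",
    "align_weights",
    "score_haplotype",
    "compute_components",
    "impute_missing_nt",
    "residualize_standardize",
]

SCORE_COLS = ["mt", "pt", "mnt", "pnt", "pgs_t", "pgs_nt"]


@dataclass
class AlignedWeights:
    """Weights matched to a marker table.

    ``index`` are positions into the marker array, ``weight`` the effect
    sizes, and ``flip`` marks markers whose declared effect allele is the
    dataset's reference (code 0) allele, so allele code a contributes as
    (1 - a).  ``mean_dosage`` is the per-marker mean haplotype dosage used
    for missing alleles.
    """

    index: np.ndarray
    weight: np.ndarray
    flip: np.ndarray
    mean_dosage: np.ndarray
    n_unmatched: int


def align_weights(
    weights: pd.DataFrame,
    gmap: GeneticMap,
    ref_allele: str = "A",
    alt_allele: str = "B",
    mean_dosage: np.ndarray | None = None,
) -> AlignedWeights:
    """Match a weight table to the dataset's markers and allele coding.

    Markers absent from the map are excluded with a logged count; a weight
    whose alleles match neither the coded (alt) nor the reference allele is an
    error.  Haplotype code 1 denotes the alt allele.
    """
    marker_pos = {m: i for i, m in enumerate(gmap.table["marker_id"])}
    idx, w, flip = [], [], []
    unmatched = 0
    for _, row in weights.iterrows():
        i = marker_pos.get(row["marker_id"])
        if i is None:
            unmatched += 1
            continue
        eff = row["effect_allele"]
        if eff == alt_allele:
            flip.append(False)
        elif eff == ref_allele:
            flip.append(True)
        else:
            raise ValueError(
                f"effect allele {eff!r} of {row['marker_id']} matches neither "
                f"dataset allele ({ref_allele}/{alt_allele})"
            )
        idx.append(i)
        w.append(float(row["weight"]))
    if unmatched:
        logger.info("%d weight-table markers not present in dataset; excluded", unmatched)
    idx = np.asarray(idx, dtype=int)
    if mean_dosage is None:
        mean_dosage = np.full(gmap.n_markers, 0.5)
    return AlignedWeights(
        idx, np.asarray(w, float), np.asarray(flip, bool),
        np.asarray(mean_dosage, float)[idx] if len(idx) else np.empty(0), unmatched,
    )


def score_haplotype(hap: np.ndarray, aligned: AlignedWeights) -> float:
    """Additive score of one haplotype: sum_j w_j x effect-allele indicator.

    Missing alleles (code -1) contribute the marker's mean haplotype dosage
    (flipped where the effect allele is the reference allele).
    """
    a = hap[aligned.index].astype(float)
    miss = a < 0
    a[miss] = aligned.mean_dosage[miss]
    a = np.where(aligned.flip, 1.0 - a, a)
    return float(np.dot(aligned.weight, a))


def compute_components(
    tmap: TransmissionMap,
    weights: pd.DataFrame,
    mean_dosage: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-offspring PGS components from a transmission map.

    Columns: mt, pt (transmitted maternal/paternal), mnt, pnt
    (non-transmitted; NaN when that parent is not genotyped), combined
    pgs_t = mt + pt and pgs_nt = mnt + pnt, plus missingness flags.  For pair
    families pgs_t is always complete because the missing parent's
    transmitted haplotype is the unassigned offspring haplotype.
    """
    aligned = align_weights(weights, tmap.gmap, mean_dosage=mean_dosage)
    rows = []
    for oid in tmap.offspring():
        rec = tmap.records[oid]
        vals = {}
        for role, short in (("mother", "m"), ("father", "p")):
            vals[f"{short}t"] = score_haplotype(rec.transmitted[role], aligned)
            nt = rec.nontransmitted[role]
            vals[f"{short}nt"] = (
                np.nan if (nt < 0).all() else score_haplotype(nt, aligned)
            )
        rows.append(
            {
                "individual_id": oid,
                "mt": vals["mt"],
                "pt": vals["pt"],
                "mnt": vals["mnt"],
                "pnt": vals["pnt"],
                "pgs_t": vals["mt"] + vals["pt"],
                "pgs_nt": vals["mnt"] + vals["pnt"],
                "mnt_missing": np.isnan(vals["mnt"]),
                "pnt_missing": np.isnan(vals["pnt"]),
                "imputed_nt": False,
            }
        )
    return pd.DataFrame(rows)


def impute_missing_nt(components: pd.DataFrame, strategy: str = "role") -> pd.DataFrame:
    """Impute missing non-transmitted scores with the observed-parent mean.

    ``strategy``:
      * ``role`` (default) — missing mothers get the observed-mother mean,
        missing fathers the observed-father mean;
      * ``overall`` — pooled mean of all observed parental NT scores.

    If no parent of the required role is observed, the pooled mean is used
    with a logged note.  The combined pgs_nt is recomputed and imputed rows
    are flagged.
    """
    if strategy not in ("role", "overall"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    out = components.copy()
    observed = np.concatenate(
        [out.loc[~out["mnt_missing"], "mnt"], out.loc[~out["pnt_missing"], "pnt"]]
    )
    pooled = float(np.mean(observed)) if len(observed) else 0.0
    for col, misscol in (("mnt", "mnt_missing"), ("pnt", "pnt_missing")):
        miss = out[misscol]
        if not miss.any():
            continue
        if strategy == "role":
            obs = out.loc[~miss, col]
            if len(obs):
                fill = float(obs.mean())
            else:
                logger.info("no observed %s scores; falling back to pooled mean", col)
                fill = pooled
        else:
            fill = pooled
        out.loc[miss, col] = fill
        out.loc[miss, "imputed_nt"] = True
    out["pgs_nt"] = out["mnt"] + out["pnt"]
    return out


def residualize_standardize(
    scores: pd.DataFrame,
    cols: list,
    pcs: pd.DataFrame | None = None,
    batches: pd.Series | None = None,
    n_pcs: int = 10,
) -> pd.DataFrame:
    """PC-residualize and z-score each score column within batch.

    Per batch, each column is replaced by its OLS residual on an intercept
    plus the first ``n_pcs`` principal components, then z-scored (ddof 0).
    With no PCs the operation reduces to a plain within-batch z-score.  New
    ``<col>_std`` columns are appended.  NaN entries are ignored in the fit
    and stay NaN.
    """
    out = scores.copy()
    n = len(out)
    if batches is None:
        batches = pd.Series(["batch0"] * n, index=out.index)
    batches = batches.reindex(out.index)
    if pcs is not None:
        pcs = pcs.reindex(out.index)
        use_pcs = pcs.iloc[:, : min(n_pcs, pcs.shape[1])].to_numpy(float)
    else:
        use_pcs = np.empty((n, 0))
    for col in cols:
        std = np.full(n, np.nan)
        x_all = out[col].to_numpy(float)
        for b in pd.unique(batches):
            in_b = (batches == b).to_numpy()
            obs = in_b & ~np.isnan(x_all)
            k = use_pcs.shape[1]
            if obs.sum() < k + 2:
                raise ValueError(
                    f"batch {b!r} has too few observations ({int(obs.sum())}) "
                    f"for {k} PCs"
                )
            X = np.column_stack([np.ones(obs.sum()), use_pcs[obs]])
            y = x_all[obs]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sd = resid.std()
            if sd < 1e-12:
                raise ValueError(
                    f"degenerate variance after residualization for {col!r} "
                    f"in batch {b!r}"
                )
            std[obs] = resid / sd
        out[f"{col}_std"] = std
    return out
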