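"""Target-decoy protein acceptance and run merging.

A protein identification run is a table with one row per (accession, run)
pair carrying the protein-level confidence score ("unused score", i.e. the
score from peptide evidence not already claimed by higher-ranking proteins),
the number of distinct peptides at the configured confidence level, sequence
coverage and a decoy flag.  Decoy entries come from matches against
reversed/shuffled sequences and calibrate the false discovery rate (FDR).

The acceptance rule implemented here: a protein is kept when, in at least
``require_in_n_runs`` runs, its unused score is strictly above that run's
FDR-derived cutoff *and* it has at least ``min_unique_peptides`` distinct
peptides.  The FDR of the accepted set is re-estimated from the decoys that
survive the filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns of a run identification table.
ID_COLUMNS = [
    "accession",
    "run_id",
    "unused_score",
    "n_unique_peptides_conf",
    "coverage",
    "is_decoy",
]

DEFAULT_DECOY_PREFIX = "DECOY_"


@dataclass
class AcceptanceResult:
    """Outcome of the target-decoy acceptance filter over all runs."""

    accepted_accessions: set[str]
    per_run_thresholds: list[float]
    residual_decoys: int
    overall_fdr: float
    #: decoy accessions that survived the filter (normally empty)
    surviving_decoy_accessions: set[str] = field(default_factory=set)

    def summary(self) -> dict:
        return {
            "thresholds": list(self.per_run_thresholds),
            "accepted_count": len(self.accepted_accessions),
            "residual_decoys": self.residual_decoys,
            "overall_fdr": self.overall_fdr,
        }


def _validate_run_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("accession", "unused_score", "is_decoy") if c not in records]
    if missing:
        raise ValueError(f"identification table lacks columns: {missing}")
    if (records["unused_score"] < 0).any():
        raise ValueError("unused_score must be nonnegative")
    return records


def estimate_fdr_threshold(records: pd.DataFrame, target_fdr: float) -> float:
    """Smallest score cutoff with decoy/target ratio at or below ``target_fdr``.

    Candidate cutoffs are the observed scores.  For each candidate ``t`` the
    FDR is estimated as ``#decoys(score >= t) / #targets(score >= t)`` (the
    simple target-decoy ratio); the smallest candidate meeting ``target_fdr``
    is returned.

    A run with no decoys already has an estimated FDR of zero everywhere, so
    the minimum observed score is returned with a warning.

    Raises
    ------
    ValueError
        On an empty table, an all-decoy table, or ``target_fdr`` outside
        (0, 1).
    """
    records = _validate_run_table(records)
    if len(records) == 0:
        raise ValueError("cannot estimate an FDR threshold from an empty run")
    if not 0 < target_fdr < 1:
        raise ValueError(f"target_fdr must be in (0, 1), got {target_fdr}")
    is_decoy = records["is_decoy"].to_numpy(dtype=bool)
    if is_decoy.all():
        raise ValueError("run contains only decoys; no targets to estimate against")

    scores = records["unused_score"].to_numpy(dtype=float)
    if not is_decoy.any():
        warnings.warn(
            "run contains no decoys; falling back to the minimum observed score",
            stacklevel=2,
        )
        return float(scores.min())

    order = np.argsort(scores)[::-1]  # descending
    sorted_scores = scores[order]
    decoy_cum = np.cumsum(is_decoy[order])
    target_cum = np.cumsum(~is_decoy[order])
    # keep, for each distinct score, the counts including all ties
    last_of_tie = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    cand_scores = sorted_scores[last_of_tie]
    cand_decoys = decoy_cum[last_of_tie]
    cand_targets = target_cum[last_of_tie]

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(cand_targets > 0, cand_decoys / cand_targets, np.inf)
    ok = fdr <= target_fdr
    if not ok.any():
        warnings.warn(
            "no score cutoff attains the requested FDR; returning the maximum score",
            stacklevel=2,
        )
        return float(cand_scores[0])
    # cand_scores descend, so the last passing candidate is the smallest
    return float(cand_scores[np.nonzero(ok)[0][-1]])


def accept_proteins(
    run_tables: list[pd.DataFrame],
    thresholds: list[float],
    min_unique_peptides: int = 2,
    require_in_n_runs: int = 1,
) -> AcceptanceResult:
    """Apply the score + unique-peptide acceptance rule across runs.

    A protein passes a run when its unused score is strictly above the run's
    threshold ("above" the cutoff) and it has at least ``min_unique_peptides``
    distinct peptides; it is accepted when it passes at least
    ``require_in_n_runs`` runs.  Decoys meeting the same rule are counted as
    residual decoys and the accepted set's FDR is
    ``residual_decoys / max(1, n_accepted)``.
    """
    if len(run_tables) != len(thresholds):
        raise ValueError(
            f"{len(run_tables)} run tables but {len(thresholds)} thresholds"
        )
    if min_unique_peptides < 0:
        raise ValueError("min_unique_peptides must be >= 0")
    if require_in_n_runs < 1:
        raise ValueError("require_in_n_runs must be >= 1")

    pass_counts: dict[str, int] = {}
    decoy_flags: dict[str, bool] = {}
    for table, thr in zip(run_tables, thresholds):
        table = _validate_run_table(table)
        passed = (table["unused_score"] > thr) & (
            table["n_unique_peptides_conf"] >= min_unique_peptides
        )
        for acc, dec in zip(table["accession"], table["is_decoy"]):
            decoy_flags[acc] = decoy_flags.get(acc, False) or bool(dec)
        for acc in table.loc[passed, "accession"]:
            pass_counts[acc] = pass_counts.get(acc, 0) + 1

    passing = {a for a, n in pass_counts.items() if n >= require_in_n_runs}
    accepted = {a for a in passing if not decoy_flags[a]}
    surviving_decoys = passing - accepted
    return AcceptanceResult(
        accepted_accessions=accepted,
        per_run_thresholds=[float(t) for t in thresholds],
        residual_decoys=len(surviving_decoys),
        overall_fdr=len(surviving_decoys) / max(1, len(accepted)),
        surviving_decoy_accessions=surviving_decoys,
    )


def merge_runs(
    run_tables: list[pd.DataFrame],
    quantified: dict[int, set[str]] | None = None,
) -> pd.DataFrame:
    """Merge per-run identification tables into one catalog by accession.

    Returns one row per accession with ``in_run_<i>`` presence flags (runs are
    numbered 1..R in the order given), the best score/coverage/peptide count
    over runs, and — when ``quantified`` maps run numbers to the accessions
    holding quantitative values in that run — ``quant_run_<i>`` flags plus a
    ``quant_class`` column partitioning the catalog into ``all`` / ``some`` /
    ``none``.
    """
    n_runs = len(run_tables)
    if n_runs == 0:
        raise ValueError("no run tables to merge")
    frames = []
    for i, table in enumerate(run_tables, start=1):
        t = _validate_run_table(table).copy()
        t["_run"] = i
        frames.append(t)
    longform = pd.concat(frames, ignore_index=True)

    catalog = (
        longform.groupby("accession")
        .agg(
            unused_score=("unused_score", "max"),
            n_unique_peptides_conf=("n_unique_peptides_conf", "max"),
            coverage=("coverage", "max"),
            is_decoy=("is_decoy", "max"),
        )
        .reset_index()
    )
    present = {
        acc: set(runs)
        for acc, runs in longform.groupby("accession")["_run"].agg(set).items()
    }
    for i in range(1, n_runs + 1):
        catalog[f"in_run_{i}"] = [int(i in present[a]) for a in catalog["accession"]]

    if quantified is not None:
        for i in range(1, n_runs + 1):
            have = quantified.get(i, set())
            catalog[f"quant_run_{i}"] = [int(a in have) for a in catalog["accession"]]
        n_quant = catalog[[f"quant_run_{i}" for i in range(1, n_runs + 1)]].sum(axis=1)
        catalog["quant_class"] = np.select(
            [n_quant == n_runs, n_quant > 0], ["all", "some"], default="none"
        )
    return catalog.sort_values("accession", ignore_index=True)


def quantitation_partition(catalog: pd.DataFrame) -> dict[str, int]:
    """Counts of catalog proteins quantified in all / some / none of the runs."""
    if "quant_class" not in catalog:
        raise ValueError("catalog carries no quantitation availability")
    counts = catalog["quant_class"].value_counts()
    return {k: int(counts.get(k, 0)) for k in ("all", "some", "none")}


def read_identifications(path) -> list[pd.DataFrame]:
    """Read a TSV identification table and split it into per-run tables.

    The file holds the columns in :data:`ID_COLUMNS`; ``is_decoy`` is 0/1.
    Tables are returned ordered by ``run_id``.
    """
    df = pd.read_csv(path, sep="\t")
    _validate_run_table(df)
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return [g.reset_index(drop=True) for _, g in df.groupby("run_id", sort=True)]
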