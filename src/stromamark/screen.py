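"""Vote-count screen over public microarray differential-expression calls.

For each gene the screen consumes the number of independent microarray
analyses that called it significantly up- or downregulated in cancer (at the
source database's p < 0.05).  A gene is *cancer_up* when at least ``up_min``
analyses called it up and at most ``down_max`` called it down; the mirrored
rule gives *cancer_down*; everything else is *unclassified*.

The bundled fixture table lists the 28 stromal-cell-enriched proteins with
their up/down vote counts; at the default thresholds (15, 1) it splits into
20 cancer-up and 8 cancer-down genes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

CANCER_UP = "cancer_up"
CANCER_DOWN = "cancer_down"
UNCLASSIFIED = "unclassified"

#: strings treated as a zero vote count in input tables
MISSING_TOKENS = {"", "-", "–", "—", "na", "nan"}


def screen_gene(n_up: int, n_down: int, up_min: int = 15, down_max: int = 1) -> str:
    """Classify one gene from its up/down vote counts.

    The up threshold is inclusive (``n_up >= up_min``); the down direction
    mirrors the same thresholds.
    """
    n_up, n_down = int(n_up), int(n_down)
    if n_up < 0 or n_down < 0:
        raise ValueError("vote counts must be nonnegative")
    if n_up >= up_min and n_down <= down_max:
        return CANCER_UP
    if n_down >= up_min and n_up <= down_max:
        return CANCER_DOWN
    return UNCLASSIFIED


def screen_catalog(
    votes: pd.DataFrame, up_min: int = 15, down_max: int = 1
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply :func:`screen_gene` to a vote table.

    ``votes`` needs columns ``gene``, ``n_up``, ``n_down`` (and optionally
    ``n_total``).  Returns ``(calls, counts)`` where ``calls`` adds a
    ``status`` column and ``counts`` tallies each status.
    """
    calls = votes.copy()
    if len(calls):
        if (calls["n_up"] < 0).any() or (calls["n_down"] < 0).any():
            raise ValueError("vote counts must be nonnegative")
        if "n_total" in calls and (
            calls["n_up"] + calls["n_down"] > calls["n_total"]
        ).any():
            raise ValueError("n_up + n_down exceeds n_total for some gene")
        calls["status"] = [
            screen_gene(u, d, up_min=up_min, down_max=down_max)
            for u, d in zip(calls["n_up"], calls["n_down"])
        ]
    else:
        calls["status"] = pd.Series(dtype=str)
    counts = {
        k: int((calls["status"] == k).sum())
        for k in (CANCER_UP, CANCER_DOWN, UNCLASSIFIED)
    }
    return calls, counts


def _parse_count(value) -> int:
    if pd.isna(value) or str(value).strip().lower() in MISSING_TOKENS:
        return 0
    return int(value)


def read_votes(path) -> pd.DataFrame:
    """Read a vote TSV; dash/missing count entries parse to 0."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("n_up", "n_down", "n_total"):
        if col in df:
            df[col] = df[col].map(_parse_count)
    return df


def load_reference_votes() -> pd.DataFrame:
    """The bundled 28-gene stromal-enriched vote table.

    Columns: accession, gene, name, unused_score, cov95_percent,
    peptides95, average_fc, n_up, n_down, n_total.
    """
    ref = resources.files("stromamark.data").joinpath("stromal_enriched_votes.tsv")
    with resources.as_file(ref) as path:
        df = read_votes(path)
    for col in ("unused_score", "cov95_percent", "average_fc"):
        df[col] = df[col].astype(float)
    df["peptides95"] = df["peptides95"].astype(int)
    return df
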