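"""Priority-ordered secretome localization classification.

Each protein carries localization evidence gathered from annotation
databases and sequence-based predictors: a set of cellular-component terms,
a classical-secretion flag (signal-peptide predictor consensus), a
non-classical-secretion flag, and the number of exosome-catalog experiments
in which the protein was detected.

Classification is a strict priority cascade:

1. *secreted* — any secreted-tier component term, or either secretion
   predictor positive;
2. *plasma_membrane* — otherwise, any membrane-tier component term;
3. *intracellular* — everything else.

Exosome-catalog membership is deliberately reported but never reclassifies:
many bona-fide intracellular proteins appear in extracellular-vesicle
compendia, and that evidence is tracked alongside the class instead of
overriding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

SECRETED = "secreted"
PLASMA_MEMBRANE = "plasma_membrane"
INTRACELLULAR = "intracellular"
CLASSES = (SECRETED, PLASMA_MEMBRANE, INTRACELLULAR)

DEFAULT_SECRETED_TERMS = frozenset(
    {"secreted", "extracellular region", "extracellular space", "extracellular matrix"}
)
DEFAULT_MEMBRANE_TERMS = frozenset(
    {"plasma membrane", "cell membrane", "cell junction"}
)


@dataclass(frozen=True)
class TermTiers:
    """Configurable term dictionaries for the two annotation tiers."""

    secreted_terms: frozenset[str] = DEFAULT_SECRETED_TERMS
    membrane_terms: frozenset[str] = DEFAULT_MEMBRANE_TERMS

    @classmethod
    def from_yaml(cls, path) -> "TermTiers":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            secreted_terms=frozenset(t.lower() for t in cfg["secreted_terms"]),
            membrane_terms=frozenset(t.lower() for t in cfg["membrane_terms"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "secreted_terms": sorted(self.secreted_terms),
                    "membrane_terms": sorted(self.membrane_terms),
                },
                fh,
            )


def _norm_terms(cc_terms) -> set[str]:
    if cc_terms is None:
        return set()
    if isinstance(cc_terms, str):
        cc_terms = cc_terms.split(";")
    return {t.strip().lower() for t in cc_terms if str(t).strip()}


def classify_localization(
    cc_terms,
    has_signal_peptide: bool = False,
    nonclassical_secreted: bool = False,
    tiers: TermTiers | None = None,
) -> tuple[str, list[str]]:
    """Classify one protein; returns ``(klass, evidence)``.

    ``evidence`` lists every fired source (matched terms and predictor
    flags), not just the first.  Term matching is case-insensitive and
    order-independent; missing predictor values are treated as negative.
    """
    tiers = tiers or TermTiers()
    terms = _norm_terms(cc_terms)
    evidence: list[str] = []
    for t in sorted(terms & tiers.secreted_terms):
        evidence.append(f"cc:{t}")
    if has_signal_peptide:
        evidence.append("signal_peptide")
    if nonclassical_secreted:
        evidence.append("nonclassical_secretion")
    if evidence:
        return SECRETED, evidence
    membrane_hits = sorted(terms & tiers.membrane_terms)
    if membrane_hits:
        return PLASMA_MEMBRANE, [f"cc:{t}" for t in membrane_hits]
    return INTRACELLULAR, []


def classify_catalog(
    annotations: pd.DataFrame, tiers: TermTiers | None = None
) -> pd.DataFrame:
    """Classify a whole annotation table.

    ``annotations`` columns: ``accession``, ``cc_terms`` (';'-joined),
    ``has_signal_peptide``, ``nonclassical_secreted``, ``exosome_hits``.
    Returns one row per accession with ``klass``, ``evidence`` (';'-joined)
    and ``exosome_hits`` carried through.
    """
    if (annotations["exosome_hits"] < 0).any():
        raise ValueError("exosome_hits must be nonnegative")
    rows = []
    for rec in annotations.itertuples(index=False):
        klass, ev = classify_localization(
            getattr(rec, "cc_terms", ""),
            bool(getattr(rec, "has_signal_peptide", False)),
            bool(getattr(rec, "nonclassical_secreted", False)),
            tiers,
        )
        rows.append(
            {
                "accession": rec.accession,
                "klass": klass,
                "evidence": ";".join(ev),
                "exosome_hits": int(rec.exosome_hits),
            }
        )
    return pd.DataFrame(rows)


def summarize_localization(calls) -> dict:
    """Counts and integer-rounded percentages per localization class.

    Accepts either a calls frame (with a ``klass`` column) or a mapping of
    class -> count.  Percentages are ``round(100 * count / total)``.
    """
    if isinstance(calls, pd.DataFrame):
        counts = {k: int((calls["klass"] == k).sum()) for k in CLASSES}
    else:
        counts = {k: int(calls.get(k, 0)) for k in CLASSES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no localization calls to summarize")
    return {
        "counts": counts,
        "total": total,
        "percent": {k: round(100 * counts[k] / total) for k in CLASSES},
    }


def exosome_overlap(calls: pd.DataFrame, min_hits: int = 1) -> dict:
    """Fraction of the catalog seen in >= ``min_hits`` exosome experiments.

    Returned overall and per localization class (NaN for an empty class).
    """
    member = calls["exosome_hits"] >= min_hits
    per_class = {}
    for k in CLASSES:
        mask = calls["klass"] == k
        per_class[k] = float(member[mask].mean()) if mask.any() else float("nan")
    return {"overall": float(member.mean()) if len(calls) else 0.0, "per_class": per_class}


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    df["has_signal_peptide"] = df["has_signal_peptide"].astype(int).astype(bool)
    df["nonclassical_secreted"] = df["nonclassical_secreted"].astype(int).astype(bool)
    df["exosome_hits"] = df["exosome_hits"].astype(int)
    return df
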