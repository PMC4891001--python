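"""Apply an REO gene-pair signature to classify samples into risk groups.

A relative expression ordering (REO) signature is a list of gene pairs, each
carrying the ordering that votes "high risk". A sample is called high risk
iff every pair votes high risk (unanimous vote); any other configuration —
including ties, which never vote high under the strict inequality — yields
low risk. Because only within-sample orderings are read, calls are invariant
to any strictly monotone per-sample transform of the expression values,
which is what makes the signature robust to batch effects and directly
portable across laboratories.

The packaged default is the published two-pair gastric cancer signature:
high risk iff KCNE2 is expressed below both PRPF3 and API5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .io import ExpressionMatrix

__all__ = ["SignaturePair", "REOSignature", "RiskCall", "classify_sample",
           "classify_cohort", "default_signature"]

ORDERINGS = ("a<b", "a>b")


@dataclass(frozen=True)
class SignaturePair:
    """One gene pair with the ordering that votes high risk."""

    gene_a: str
    gene_b: str
    high_risk_order: str  # "a<b" means Ea < Eb votes high risk

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"pair genes must differ, got {self.gene_a!r} twice")
        if self.high_risk_order not in ORDERINGS:
            raise ValueError(f"high_risk_order must be one of {ORDERINGS}")

    def vote_high(self, ea: float, eb: float) -> bool:
        """Strict-inequality vote; a tie (Ea == Eb) never votes high."""
        return ea < eb if self.high_risk_order == "a<b" else ea > eb


@dataclass
class REOSignature:
    """An ordered list of signature pairs plus the unanimous-vote rule."""

    pairs: list
    name: str = "custom"
    note: str = ""

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("a signature needs at least one pair")
        self.pairs = [p if isinstance(p, SignaturePair) else SignaturePair(*p)
                      for p in self.pairs]

    @property
    def genes(self) -> list:
        seen: dict = {}
        for p in self.pairs:
            seen.setdefault(p.gene_a)
            seen.setdefault(p.gene_b)
        return list(seen)

    def to_json(self, path=None) -> str:
        doc = {"name": self.name, "note": self.note,
               "pairs": [{"gene_a": p.gene_a, "gene_b": p.gene_b,
                          "high_risk_order": p.high_risk_order}
                         for p in self.pairs]}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "REOSignature":
        text = Path(source).read_text() if not str(source).lstrip().startswith("{") \
            else str(source)
        doc = json.loads(text)
        pairs = [SignaturePair(p["gene_a"], p["gene_b"], p["high_risk_order"])
                 for p in doc["pairs"]]
        return cls(pairs=pairs, name=doc.get("name", "custom"),
                   note=doc.get("note", ""))


def default_signature() -> REOSignature:
    """The packaged two-pair 5-FU gastric cancer signature (KCNE2/PRPF3/API5)."""
    text = resources.files("reosig").joinpath("assets/signature_5fu_gc.json").read_text()
    return REOSignature.from_json(text)


@dataclass
class RiskCall:
    """Per-sample classification with the individual pair votes."""

    sample_id: str
    label: str                   # "high" | "low"
    votes: list = field(default_factory=list)  # per-pair booleans, high==True
    n_missing_genes: int = 0

    def __post_init__(self) -> None:
        expected = "high" if self.votes and all(self.votes) else "low"
        assert self.label == expected, "label must equal the unanimous vote"


def classify_sample(expr_vector: pd.Series, sig: REOSignature,
                    missing: str = "error") -> RiskCall:
    """Classify one sample from its gene -> expression mapping.

    ``missing="error"`` (default) refuses to classify when a signature gene
    is absent — a partial signature is a different rule. ``missing="low"``
    downgrades the call to low risk and records the count.
    """
    if missing not in ("error", "low"):
        raise ValueError("missing policy must be 'error' or 'low'")
    absent = [g for g in sig.genes if g not in expr_vector.index]
    if absent:
        if missing == "error":
            raise KeyError(f"signature gene(s) missing from sample: {absent}")
        return RiskCall(sample_id=str(expr_vector.name), label="low",
                        votes=[False] * len(sig.pairs),
                        n_missing_genes=len(absent))
    votes = [p.vote_high(float(expr_vector[p.gene_a]), float(expr_vector[p.gene_b]))
             for p in sig.pairs]
    label = "high" if all(votes) else "low"
    return RiskCall(sample_id=str(expr_vector.name), label=label, votes=votes)


def classify_cohort(expr: ExpressionMatrix, sig: REOSignature,
                    missing: str = "error") -> pd.DataFrame:
    """Classify every sample of a cohort; output order follows input order.

    Returns a samples-indexed frame with the label, one boolean vote column
    per pair, and the missing-gene count.
    """
    calls = [classify_sample(expr.values[s], sig, missing=missing)
             for s in expr.sample_ids]
    out = pd.DataFrame({
        "label": [c.label for c in calls],
        "n_missing_genes": [c.n_missing_genes for c in calls],
    }, index=pd.Index(expr.sample_ids, name="sample_id"))
    for i, p in enumerate(sig.pairs):
        out[f"vote_{p.gene_a}_{p.gene_b}"] = [c.votes[i] for c in calls]
    return out
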