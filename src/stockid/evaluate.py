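"""Cohort-level evaluation of consensus assignments.

Rates follow the mixed-stock reporting convention: the assignment rate is
the fraction of the cohort with a consensus label, and the agreement rate
is computed among the *assigned* subset (the fraction whose consensus label
equals the traditional label); the full-cohort denominator is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assign import UNASSIGNED


@dataclass
class AgreementReport:
    n_total: int
    n_assigned: int
    assignment_rate: float
    n_agree: int
    agreement_rate: float            # n_agree / n_assigned
    agreement_rate_of_total: float   # n_agree / n_total
    per_label: pd.DataFrame          # index: traditional label
    confusion: pd.DataFrame          # traditional x consensus (incl. UNASSIGNED)
    replicate_pairs_total: int
    replicate_pairs_identical: int

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_assigned": self.n_assigned,
            "assignment_rate": self.assignment_rate,
            "n_agree": self.n_agree,
            "agreement_rate": self.agreement_rate,
            "agreement_rate_of_total": self.agreement_rate_of_total,
            "per_label": self.per_label.reset_index().to_dict(orient="records"),
            "confusion": {
                t: {c: int(v) for c, v in row.items()}
                for t, row in self.confusion.to_dict(orient="index").items()
            },
            "replicate_pairs_total": self.replicate_pairs_total,
            "replicate_pairs_identical": self.replicate_pairs_identical,
            "denominator_note": (
                "agreement_rate uses the assigned subset as denominator; "
                "per-label rates use that traditional label's individuals"
            ),
        }


def evaluate_cohort(
    consensus: pd.DataFrame,
    traditional_labels: dict[str, str],
    replicate_pairs: list[tuple[str, str]] | None = None,
    count_double_unassigned_as_identical: bool = False,
) -> AgreementReport:
    """Assignment/agreement rates, confusion table and replicate concordance.

    ``consensus`` is the frame from :func:`stockid.assign.consensus_assign`.
    A replicate pair is "identical" iff both members carry the same consensus
    label; a pair that is UNASSIGNED on both sides counts as identical only
    when ``count_double_unassigned_as_identical`` is set.
    """
    missing = [s for s in consensus["sample_id"] if s not in traditional_labels]
    if missing:
        raise KeyError(f"samples without traditional label: {missing[:5]}")
    df = consensus.copy()
    df["traditional"] = [traditional_labels[s] for s in df["sample_id"]]
    n_total = len(df)
    assigned = df[df["consensus"] != UNASSIGNED]
    n_assigned = len(assigned)
    n_agree = int((assigned["consensus"] == assigned["traditional"]).sum())

    labels = sorted(set(df["traditional"]))
    cons_labels = sorted(set(df["consensus"]) - {UNASSIGNED} | set(labels))
    confusion = pd.DataFrame(
        0, index=labels, columns=cons_labels + [UNASSIGNED], dtype=int
    )
    for _, row in df.iterrows():
        confusion.loc[row["traditional"], row["consensus"]] += 1

    per_rows = []
    for lbl in labels:
        sub = df[df["traditional"] == lbl]
        sub_assigned = sub[sub["consensus"] != UNASSIGNED]
        n_l, na_l = len(sub), len(sub_assigned)
        agree_l = int((sub_assigned["consensus"] == lbl).sum())
        per_rows.append(
            {
                "traditional_label": lbl,
                "n": n_l,
                "n_assigned": na_l,
                "assignment_rate": na_l / n_l if n_l else np.nan,
                "agreement_rate": agree_l / na_l if na_l else np.nan,
            }
        )
    per_label = pd.DataFrame(per_rows).set_index("traditional_label")

    pairs = replicate_pairs or []
    cons_of = dict(zip(df["sample_id"], df["consensus"]))
    ident = 0
    for a, b in pairs:
        if a not in cons_of or b not in cons_of:
            raise KeyError(f"replicate pair ({a!r}, {b!r}) references unknown sample")
        ca, cb = cons_of[a], cons_of[b]
        if ca == cb and (
            ca != UNASSIGNED or count_double_unassigned_as_identical
        ):
            ident += 1

    return AgreementReport(
        n_total=n_total,
        n_assigned=n_assigned,
        assignment_rate=n_assigned / n_total if n_total else np.nan,
        n_agree=n_agree,
        agreement_rate=n_agree / n_assigned if n_assigned else np.nan,
        agreement_rate_of_total=n_agree / n_total if n_total else np.nan,
        per_label=per_label,
        confusion=confusion,
        replicate_pairs_total=len(pairs),
        replicate_pairs_identical=ident,
    )


def composition_by_label(
    consensus: pd.DataFrame, traditional_labels: dict[str, str]
) -> pd.DataFrame:
    """Fraction of each traditional label's individuals per consensus label.

    Rows (traditional labels) sum to 1; UNASSIGNED is a column.  This is the
    pie-chart-style composition of genetic assignments within each
    traditionally labelled group.
    """
    missing = [s for s in consensus["sample_id"] if s not in traditional_labels]
    if missing:
        raise KeyError(f"samples without traditional label: {missing[:5]}")
    df = consensus.copy()
    df["traditional"] = [traditional_labels[s] for s in df["sample_id"]]
    tab = (
        df.groupby(["traditional", "consensus"]).size().unstack(fill_value=0)
    )
    for col in [UNASSIGNED]:
        if col not in tab.columns:
            tab[col] = 0
    tab = tab.div(tab.sum(axis=1), axis=0)
    return tab


def round_percent(x: float, digits: int = 1) -> float:
    """Half-up percentage rounding for human-readable output."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -digits
    return float(Decimal(str(x * 100)).quantize(q, rounding=ROUND_HALF_UP))
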