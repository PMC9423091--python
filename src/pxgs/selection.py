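"""Selection accounting: top-fraction selection, expected gain, status
number, and cross-model corrected gain.

Expected genetic gain is reported the way tree-breeding programs quote
it: the mean predicted breeding value of the selected set as a percentage
of the population phenotypic mean on the modeling scale.  Genetic
diversity of a selected set is summarized by the status number
``Ns = 1 / (2 theta)`` where ``theta`` is the group coancestry — the
number of unrelated, non-inbred individuals carrying equivalent gene
diversity.  A reference model (typically the genomic one) supplies
corrected breeding values for sets selected under a less reliable model,
quantifying gain overestimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import IntegrityError, RelationshipMatrix, compute_A_additive


class UsageError(ValueError):
    pass


@dataclass
class SelectionReport:
    model_label: str
    selected_ids: list
    mean_bv: float
    gain_percent: float
    status_number: float | None = None
    corrected_mean_bv: float | None = None
    corrected_gain_percent: float | None = None
    overlap_percent_vs_reference: float | None = None
    overestimation_percent: float | None = None


def select_top(bvs: pd.Series, fraction: float | None = None,
               count: int | None = None) -> list:
    """Ids of the highest-breeding-value individuals.

    Exactly one of ``fraction`` or ``count`` must be given; ties at the
    cutoff are broken by id order (with a warning).
    """
    if bvs.empty:
        raise UsageError("empty breeding-value set")
    if (fraction is None) == (count is None):
        raise UsageError("give exactly one of fraction or count")
    n = count if count is not None else int(round(fraction * len(bvs)))
    if n > len(bvs):
        raise UsageError("selection count exceeds population size")
    if n == 0:
        return []
    ordered = bvs.sort_index().sort_values(ascending=False, kind="stable")
    cutoff = ordered.iloc[n - 1]
    if n < len(ordered) and ordered.iloc[n] == cutoff:
        warnings.warn("tie at the selection cutoff; broken by id order")
    return list(ordered.index[:n])


def status_number(rel, ids) -> float:
    """Status number ``Ns = 1/(2 theta)`` of a set of individuals.

    ``theta`` is the group coancestry: the mean over all ordered pairs
    (self-pairs included) of the pairwise coancestry, which is half the
    additive relationship (self-coancestry is half the matrix diagonal).
    ``rel`` may be a relationship matrix or a pedigree table (from which
    the numerator relationship matrix is built).
    """
    if isinstance(rel, pd.DataFrame):
        rel = compute_A_additive(rel)
    if not isinstance(rel, RelationshipMatrix):
        raise UsageError("rel must be a RelationshipMatrix or a pedigree table")
    ids = list(ids)
    if not ids:
        raise UsageError("empty selection")
    sub = rel.submatrix(ids).values
    theta = float(sub.mean()) / 2.0
    if theta <= 0:
        raise ZeroDivisionError("zero group coancestry; status number undefined")
    return 1.0 / (2.0 * theta)


def expected_gain(bvs: pd.Series, selected_ids, population_phenotypic_mean: float
                  ) -> float:
    """Expected genetic gain percent.

    ``100 * mean(BV of selected) / population phenotypic mean``, both on
    the modeling scale (the log scale for log-modeled traits).
    """
    if population_phenotypic_mean == 0:
        raise ZeroDivisionError("zero population mean; gain percentage undefined")
    sel = bvs.loc[list(selected_ids)]
    return float(100.0 * sel.mean() / population_phenotypic_mean)


def corrected_gain(
    bvs_model: pd.Series,
    bvs_reference: pd.Series,
    population_phenotypic_mean: float,
    fraction: float | None = None,
    count: int | None = None,
    model_label: str = "model",
    rel_for_ns=None,
) -> SelectionReport:
    """Score a model's selection and correct it against a reference model.

    Selects the top set under ``bvs_model``, then re-evaluates that set
    with the reference model's breeding values: corrected mean BV and
    gain, percent overlap with the reference model's own selection, and
    the gain overestimation percent of the nominal gain relative to the
    corrected one.
    """
    if set(bvs_model.index) != set(bvs_reference.index):
        raise IntegrityError("models score different individuals")
    sel = select_top(bvs_model, fraction=fraction, count=count)
    sel_ref = select_top(bvs_reference, fraction=fraction, count=count)
    gain = expected_gain(bvs_model, sel, population_phenotypic_mean)
    corr_mean = float(bvs_reference.loc[sel].mean())
    corr_gain = expected_gain(bvs_reference, sel, population_phenotypic_mean)
    overlap = 100.0 * len(set(sel) & set(sel_ref)) / len(sel_ref) if sel_ref else 0.0
    over = (100.0 * (gain - corr_gain) / corr_gain) if corr_gain != 0 else None
    ns = status_number(rel_for_ns, sel) if rel_for_ns is not None else None
    return SelectionReport(
        model_label=model_label, selected_ids=sel,
        mean_bv=float(bvs_model.loc[sel].mean()), gain_percent=gain,
        status_number=ns, corrected_mean_bv=corr_mean,
        corrected_gain_percent=corr_gain,
        overlap_percent_vs_reference=overlap,
        overestimation_percent=over,
    )
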