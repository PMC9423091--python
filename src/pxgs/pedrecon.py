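"""Pedigree verification and reconstruction from genomic relationships.

A polycross trial records only the mother of each offspring; fathers come
from a pooled pollen mix and the maternal records themselves carry errors.
Because a realized genomic relationship matrix concentrates parent-
offspring pairs near 0.5 and unrelated pairs near 0, simple thresholded
argmax rules recover the pedigree:

* maternity is verified (and mislabels corrected) by the female with the
  maximum relationship to each offspring;
* recorded families whose offspring split into a mother-related and a
  mother-unrelated but internally half-sib-coherent group reveal mothers
  with two possible genotypes, and the family is divided;
* paternity is the male with maximum relationship, confirmed by
  within-paternal-family sib coherence; offspring related to no candidate
  male are pollen contaminants; offspring nearly identical to their mother
  and without a distinct father are selfs;
* near-unity pairs among offspring are duplicate genotyped samples.

The χ² contribution test quantifies deviation from the equal-male-
contribution assumption of the polycross design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relmat import IntegrityError, RelationshipMatrix


class ConfigurationError(ValueError):
    pass


@dataclass
class ThresholdConfig:
    """Relationship thresholds for reconstruction decisions.

    ``parent_offspring_min`` / ``halfsib_min`` are the classic 0.15 / 0.07
    cutoffs for declaring a parent-offspring or half-sib relationship;
    ``duplicate_min`` separates duplicates (~0.9) from full sibs (~0.5);
    ``self_parent_min`` separates a self's relationship to its parent (~1)
    from an outcrossed offspring's (~0.5); ``split_min_group`` is the
    minimum subgroup size before a dual-genotype family split is declared.
    """

    parent_offspring_min: float = 0.15
    halfsib_min: float = 0.07
    duplicate_min: float = 0.80
    self_parent_min: float = 0.70
    split_min_group: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.halfsib_min < self.parent_offspring_min
                < self.self_parent_min < self.duplicate_min <= 2.0):
            raise ConfigurationError(
                "thresholds must satisfy 0 < halfsib < parent_offspring "
                "< self_parent < duplicate <= 2")


@dataclass
class FamilySplit:
    mother_id: str
    group_a: list
    group_b: list
    is_split: bool
    new_mother_label: str | None = None


@dataclass
class ContributionTest:
    counts_per_male: np.ndarray
    expected_count: float
    chi2: float
    df: int
    p_value: float


@dataclass
class ReconstructionResult:
    assignments: pd.DataFrame
    pedigree: pd.DataFrame
    splits: list
    duplicates: list
    contribution: ContributionTest | None
    family_summary: pd.DataFrame


def _argmax_with_ties(rel: np.ndarray, candidate_ids: np.ndarray) -> tuple[str, float]:
    """Best candidate by relationship; ties broken by lowest-sorting id."""
    best = rel.max()
    tied = np.flatnonzero(rel >= best - 1e-12)
    if len(tied) > 1:
        warnings.warn("tie in maximal relationship; choosing lowest-sorting id")
        winner = min(candidate_ids[tied])
    else:
        winner = candidate_ids[tied[0]]
    return winner, float(best)


def verify_maternity(G: RelationshipMatrix, recorded: pd.DataFrame,
                     female_ids, th: ThresholdConfig | None = None) -> pd.DataFrame:
    """Confirm or correct the recorded mother of each offspring.

    For each offspring the candidate mother is the genotyped female with
    the maximum relationship; she is confirmed if that maximum reaches
    ``parent_offspring_min``.  Disagreements with the record are flagged
    as pedigree errors; offspring with no female above threshold are
    ``mother_unassigned``.
    """
    th = th or ThresholdConfig()
    females = np.asarray([f for f in female_ids if f in set(G.ids)], dtype=object)
    rec = recorded.set_index("id")["mother"]
    rec = rec[rec.notna()]  # founders carry no recorded mother
    off_ids = [i for i in rec.index if i in set(G.ids)]
    missing = set(rec.index) - set(G.ids)
    if missing:
        raise IntegrityError(f"offspring absent from G: {sorted(map(str, missing))[:5]}")
    fidx = G.index(females)
    rows = []
    for off in off_ids:
        oi = G.index([off])[0]
        rel = G.values[oi, fidx]
        best_female, best_rel = _argmax_with_ties(rel, females)
        confirmed = best_female if best_rel >= th.parent_offspring_min else None
        recorded_mother = rec[off]
        rows.append({
            "offspring_id": off,
            "recorded_mother": recorded_mother,
            "best_female": best_female,
            "mother_relationship": best_rel,
            "confirmed_mother": confirmed,
            "pedigree_error": confirmed is not None and confirmed != recorded_mother,
            "mother_unassigned": confirmed is None,
        })
    return pd.DataFrame(rows)


def detect_family_split(G: RelationshipMatrix, family_offspring, mother_id,
                        th: ThresholdConfig | None = None,
                        max_unrelated_pair_fraction: float = 0.2) -> FamilySplit:
    """Test one maternal family for a hidden second mother genotype.

    Offspring are partitioned by their relationship to the genotyped
    mother.  A split is declared only when both groups reach
    ``split_min_group``, the mother-unrelated group is internally
    half-sib coherent (mean pairwise relationship >= ``halfsib_min``),
    and at most ``max_unrelated_pair_fraction`` of its internal pairs fall
    below ``halfsib_min`` (no residual peak at zero relationship).
    """
    th = th or ThresholdConfig()
    fam = np.asarray(list(family_offspring), dtype=object)
    if mother_id not in set(G.ids):
        return FamilySplit(mother_id, [], list(fam), False)
    mi = G.index([mother_id])[0]
    rel_to_mother = G.values[G.index(fam), mi]
    related = rel_to_mother >= th.parent_offspring_min
    group_a, group_b = list(fam[related]), list(fam[~related])
    if len(group_a) < th.split_min_group or len(group_b) < th.split_min_group:
        return FamilySplit(mother_id, group_a, group_b, False)
    bidx = G.index(group_b)
    sub = G.values[np.ix_(bidx, bidx)]
    iu = np.triu_indices(len(group_b), k=1)
    pair_rel = sub[iu]
    coherent = pair_rel.mean() >= th.halfsib_min
    stray_fraction = float((pair_rel < th.halfsib_min).mean())
    is_split = bool(coherent and stray_fraction <= max_unrelated_pair_fraction)
    label = f"{mother_id}_hidden" if is_split else None
    return FamilySplit(mother_id, group_a, group_b, is_split, label)


def assign_paternity(G: RelationshipMatrix, offspring_mothers: pd.DataFrame,
                     male_ids, th: ThresholdConfig | None = None) -> pd.DataFrame:
    """Assign fathers from the candidate male pool.

    The father is the candidate male with the maximum relationship if it
    reaches ``parent_offspring_min``; otherwise the offspring is a pollen
    contaminant.  A confirmation pass demotes offspring whose mean
    relationship to their assembled paternal half-sib family falls below
    ``halfsib_min``.  Offspring related to their mother at
    ``self_parent_min`` or above without a distinct qualifying father are
    selfs.

    ``offspring_mothers`` needs columns ``offspring_id`` and ``mother``
    (the resolved mother id or None).
    """
    th = th or ThresholdConfig()
    males = np.asarray(list(male_ids), dtype=object)
    if len(males) == 0:
        raise ConfigurationError("empty candidate male list")
    males_in_G = np.asarray([m for m in males if m in set(G.ids)], dtype=object)
    if len(males_in_G) == 0:
        raise ConfigurationError("no candidate male is genotyped")
    midx = G.index(males_in_G)
    rows = []
    for _, r in offspring_mothers.iterrows():
        off, mother = r["offspring_id"], r["mother"]
        oi = G.index([off])[0]
        rel = G.values[oi, midx]
        best_male, best_rel = _argmax_with_ties(rel, males_in_G)
        mother_rel = (G.values[oi, G.index([mother])[0]]
                      if (mother is not None and pd.notna(mother) and mother in set(G.ids))
                      else np.nan)
        father, status = None, "contaminant"
        if best_rel >= th.parent_offspring_min:
            father, status = best_male, "assigned"
        if (np.isfinite(mother_rel) and mother_rel >= th.self_parent_min
                and (father is None or father == mother)):
            father, status = mother, "self"
        rows.append({"offspring_id": off, "mother": mother, "assigned_father": father,
                     "father_relationship": best_rel, "mother_relationship": mother_rel,
                     "status": status})
    out = pd.DataFrame(rows)

    # confirmation pass: within each paternal half-sib family, an assigned
    # offspring must be coherent with its co-members
    for father, fam in out[out["status"] == "assigned"].groupby("assigned_father"):
        ids = fam["offspring_id"].to_numpy(object)
        if len(ids) < 2:
            continue
        idx = G.index(ids)
        sub = G.values[np.ix_(idx, idx)]
        mean_rel = (sub.sum(axis=1) - np.diag(sub)) / (len(ids) - 1)
        demote = ids[mean_rel < th.halfsib_min]
        if len(demote):
            sel = out["offspring_id"].isin(demote)
            out.loc[sel, "status"] = "contaminant"
            out.loc[sel, "assigned_father"] = None
    return out


def detect_duplicates(G: RelationshipMatrix, th: ThresholdConfig | None = None,
                      missing_counts: dict | None = None) -> list:
    """All unordered pairs with relationship >= ``duplicate_min``.

    Returns (id_a, id_b, relationship, flagged_for_removal) tuples; the
    member with more missing genotype calls (if counts are supplied,
    otherwise the higher-sorting id) is flagged for removal.
    """
    th = th or ThresholdConfig()
    iu = np.triu_indices(G.n, k=1)
    hits = np.flatnonzero(G.values[iu] >= th.duplicate_min)
    pairs = []
    for k in hits:
        a, b = G.ids[iu[0][k]], G.ids[iu[1][k]]
        if missing_counts is not None:
            drop = a if missing_counts.get(a, 0) > missing_counts.get(b, 0) else b
        else:
            drop = max(a, b)
        pairs.append((a, b, float(G.values[iu[0][k], iu[1][k]]), drop))
    return pairs


def test_equal_contribution(counts_per_male) -> ContributionTest:
    """χ² goodness-of-fit test against equal male contribution.

    ``counts_per_male`` are assigned-offspring counts per polymix male,
    excluding contaminants and selfs.
    """
    counts = np.asarray(counts_per_male, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no assigned offspring; contribution test undefined")
    k = len(counts)
    expected = total / k
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return ContributionTest(counts.astype(int), expected, chi2, df, p)


def build_fs_pedigree(assignments: pd.DataFrame, recorded: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the reconstructed full-sib pedigree.

    Offspring with status ``assigned`` get their confirmed mother and
    assigned father; contaminants keep the confirmed mother with an
    unknown father; selfs get mother = father; ``mother_unassigned`` and
    ``duplicate`` offspring keep both parents unknown (duplicates are
    flagged for removal but stay addressable in the pedigree).  Returns
    the pedigree (founders first) and a full-sib family-size summary.
    """
    founders = recorded[recorded["mother"].isna() & recorded["father"].isna()]
    hidden = sorted({m for m in assignments["mother"].dropna()
                     if m not in set(recorded["id"])})
    off = pd.DataFrame({
        "id": assignments["offspring_id"],
        "mother": assignments["mother"],
        "father": assignments["assigned_father"],
    })
    ped = pd.concat([
        founders[["id", "mother", "father"]],
        pd.DataFrame({"id": hidden, "mother": pd.NA, "father": pd.NA}),
        off,
    ], ignore_index=True)
    fs = assignments[assignments["status"].isin(["assigned", "self"])]
    sizes = fs.groupby(["mother", "assigned_father"]).size()
    summary = pd.DataFrame({
        "n_fs_families": [len(sizes)],
        "min_size": [int(sizes.min()) if len(sizes) else 0],
        "max_size": [int(sizes.max()) if len(sizes) else 0],
        "mean_size": [float(sizes.mean()) if len(sizes) else 0.0],
    })
    return ped, summary


def reconstruct_pedigree(G: RelationshipMatrix, recorded: pd.DataFrame,
                         female_ids, male_ids,
                         th: ThresholdConfig | None = None) -> ReconstructionResult:
    """Full reconstruction: duplicates → maternity → family splits →
    paternity (incl. selfs) → contribution test → corrected pedigree."""
    th = th or ThresholdConfig()
    parents = set(female_ids) | set(male_ids)
    offspring_ids = [i for i in G.ids if i not in parents]
    Goff = G.submatrix(offspring_ids)
    duplicates = detect_duplicates(Goff, th)
    drop = {d for *_, d in duplicates}

    maternity = verify_maternity(G, recorded, female_ids, th)
    maternity = maternity[~maternity["offspring_id"].isin(drop)].reset_index(drop=True)

    # family splits operate on corrected family membership: offspring grouped
    # by confirmed mother, with the unassigned kept under their recorded mother
    mother_now = maternity["confirmed_mother"].where(
        maternity["confirmed_mother"].notna(), maternity["recorded_mother"])
    fam_of = dict(zip(maternity["offspring_id"], mother_now))
    splits = []
    resolved = dict(zip(maternity["offspring_id"],
                        maternity["confirmed_mother"]))
    split_ids: dict[str, str] = {}
    for mother in sorted(set(fam_of.values())):
        fam = [o for o, m in fam_of.items() if m == mother]
        s = detect_family_split(G, fam, mother, th)
        splits.append(s)
        if s.is_split:
            for o in s.group_b:
                resolved[o] = s.new_mother_label
                split_ids[o] = s.new_mother_label

    off_mothers = pd.DataFrame({
        "offspring_id": list(resolved),
        "mother": [resolved[o] for o in resolved],
    })
    paternity = assign_paternity(G, off_mothers, male_ids, th)
    assignments = maternity.merge(paternity, on="offspring_id")
    assignments["family_split_id"] = assignments["offspring_id"].map(split_ids)
    unassigned = assignments["mother"].isna()
    assignments.loc[unassigned, "status"] = "mother_unassigned"
    dup_rows = pd.DataFrame({
        "offspring_id": sorted(drop),
        "status": "duplicate",
    })
    assignments = pd.concat([assignments, dup_rows], ignore_index=True)

    assigned = assignments[assignments["status"] == "assigned"]
    genotyped_males = [m for m in male_ids if m in set(G.ids)]
    counts = assigned["assigned_father"].value_counts()
    count_vec = np.array([counts.get(m, 0) for m in genotyped_males])
    contribution = (test_equal_contribution(count_vec)
                    if count_vec.sum() > 0 else None)

    ped, summary = build_fs_pedigree(assignments, recorded)
    return ReconstructionResult(assignments, ped, splits, duplicates,
                                contribution, summary)
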