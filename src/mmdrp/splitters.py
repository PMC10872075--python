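"""Leakage-free k-fold splitting of drug-response records.

Four grouping schemes, each guaranteeing that the grouping key never appears
on both sides of a fold:

* ``cell_line``   — unseen cell lines in validation;
* ``drug_scaffold`` — unseen Bemis-Murcko scaffolds (stricter than unseen
  drug names, since close analogues share a scaffold);
* ``both``        — simultaneously unseen cell lines *and* scaffolds: cell
  lines and scaffolds are partitioned independently; fold i validates on
  (cell-line group i x scaffold group i), trains on records touching
  neither, and discards the mixed quadrants;
* ``cancer_type`` — unseen lineages (verbatim lineage strings).

Groups are shuffled by seed and dealt greedily to balance fold sizes by
record count; ties break on lexical group name for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import OmicMatrix, ResponseRecord

__all__ = ["FoldAssignment", "split", "complete_profile_filter", "SCHEMES"]

SCHEMES = ("cell_line", "drug_scaffold", "both", "cancer_type")


@dataclass
class FoldAssignment:
    scheme: str
    fold: int
    train_indices: list[int]
    validation_indices: list[int]
    discarded_indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.train_indices) & set(self.validation_indices)
        if overlap:
            raise ValueError(f"train/validation overlap: {sorted(overlap)[:5]}")


def _partition_groups(keys: list[str], record_counts: dict[str, int],
                      k_folds: int, rng: np.random.Generator) -> dict[str, int]:
    """Deal groups into k folds, balancing record counts.

    Groups are lexically sorted (reproducible base order), shuffled with the
    seed, then dealt in shuffled order to the currently lightest fold (ties
    go to the lowest fold index).
    """
    keys = sorted(set(keys))
    if len(keys) < k_folds:
        raise ValueError(
            f"cannot make {k_folds} folds from {len(keys)} distinct groups")
    shuffled = [keys[i] for i in rng.permutation(len(keys))]
    loads = np.zeros(k_folds)
    assignment: dict[str, int] = {}
    for g in shuffled:
        fold = int(np.argmin(loads))
        assignment[g] = fold
        loads[fold] += record_counts[g]
    return assignment


def _group_key(record: ResponseRecord, scheme: str,
               scaffold_map: dict[str, str] | None) -> str:
    if scheme == "cell_line":
        return record.cell_line
    if scheme == "cancer_type":
        return record.lineage
    if scheme in ("drug_scaffold", "both"):
        if scaffold_map is None or record.drug not in scaffold_map:
            raise ValueError(f"no scaffold for drug {record.drug!r}")
        return scaffold_map[record.drug]
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def split(records: list[ResponseRecord], scheme: str, k_folds: int = 5,
          seed: int = 0, scaffold_map: dict[str, str] | None = None
          ) -> list[FoldAssignment]:
    """Partition records into ``k_folds`` leakage-free folds."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    rng = np.random.default_rng(seed)

    if scheme != "both":
        keys = [_group_key(r, scheme, scaffold_map) for r in records]
        counts: dict[str, int] = {}
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
        fold_of = _partition_groups(keys, counts, k_folds, rng)
        folds = []
        for k in range(k_folds):
            val = [i for i, key in enumerate(keys) if fold_of[key] == k]
            train = [i for i, key in enumerate(keys) if fold_of[key] != k]
            folds.append(FoldAssignment(scheme, k, train, val))
        return folds

    # scheme == "both": independent partitions of cell lines and scaffolds
    cl_keys = [r.cell_line for r in records]
    sc_keys = [_group_key(r, "drug_scaffold", scaffold_map) for r in records]
    cl_counts: dict[str, int] = {}
    sc_counts: dict[str, int] = {}
    for c, s in zip(cl_keys, sc_keys):
        cl_counts[c] = cl_counts.get(c, 0) + 1
        sc_counts[s] = sc_counts.get(s, 0) + 1
    cl_fold = _partition_groups(cl_keys, cl_counts, k_folds, rng)
    sc_fold = _partition_groups(sc_keys, sc_counts, k_folds, rng)
    folds = []
    for k in range(k_folds):
        val, train, discarded = [], [], []
        for i, (c, s) in enumerate(zip(cl_keys, sc_keys)):
            cell_in_val = cl_fold[c] == k
            scaf_in_val = sc_fold[s] == k
            if cell_in_val and scaf_in_val:
                val.append(i)
            elif not cell_in_val and not scaf_in_val:
                train.append(i)
            else:  # mixed quadrant: would leak one key into training
                discarded.append(i)
        folds.append(FoldAssignment(scheme, k, train, val, discarded))
    return folds


def complete_profile_filter(records: list[ResponseRecord],
                            matrices: list[OmicMatrix]
                            ) -> tuple[list[ResponseRecord], dict]:
    """Keep records whose cell line appears in *every* supplied omic matrix.

    Emulates the restricted complete-profile subset used for fair
    cross-modality comparisons. Returns the filtered records plus a summary
    of retention counts and percentages.
    """
    if not matrices:
        raise ValueError("need at least one omic matrix")
    panels = [set(m.cell_lines) for m in matrices]
    complete = set.intersection(*panels)
    all_cell_lines = {r.cell_line for r in records}
    kept = [r for r in records if r.cell_line in complete]
    summary = {
        "n_cell_lines_total": len(all_cell_lines),
        "n_cell_lines_complete": len(all_cell_lines & complete),
        "n_records_total": len(records),
        "n_records_kept": len(kept),
        "pct_cell_lines_kept": (100.0 * len(all_cell_lines & complete)
                                / len(all_cell_lines)) if all_cell_lines else 0.0,
        "pct_records_kept": (100.0 * len(kept) / len(records)) if records else 0.0,
    }
    return kept, summary
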