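"""Full study orchestration: main contrast, within-group pairs, exclusions.

The study design is: one main two-group contrast analysed with both the
univariate (smoothed Weir-Cockerham F_ST outliers) and multivariate
(hierarchical stepwise + canonical discriminant) branches, plus every
within-group breed-pair contrast analysed the same way.  Markers flagged by
both branches in the main contrast form the *common* set; any marker also
flagged in a within-group pairwise contrast reflects breed differentiation
rather than group-level divergence and is excluded.  The survivors are the
final candidate markers, refitted alone by CDA and once more with a
stepwise augmentation run that keeps them forced in.

Everything is deterministic given dataset + config: tie-breaks follow map
order and no randomness is introduced.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discriminant import (CdaResult, SdaParams, SdaResult, cda_fit,
                           cda_refit_with_augmentation, hierarchical_sda,
                           mean_impute)
from .fst_scan import FstScanResult, OutlierParams, SmoothParams, fst_scan
from .genotype_io import GenotypeDataset


@dataclass
class PipelineParams:
    smooth: SmoothParams = field(default_factory=SmoothParams)
    outlier: OutlierParams = field(default_factory=OutlierParams)
    sda: SdaParams = field(default_factory=SdaParams)
    exclusion_mode: str = "common_only"  # or "union_both_methods"
    positive_group: str | None = None

    def __post_init__(self) -> None:
        if self.exclusion_mode not in ("union_both_methods", "common_only"):
            raise ValueError("unknown exclusion mode")


@dataclass
class ComparisonResult:
    """Both branches applied to one population contrast."""

    label: str
    fst_outliers: set[str]
    cda_selected: set[str]
    fst_result: FstScanResult | None = None
    sda_result: SdaResult | None = None
    cda_result: CdaResult | None = None

    @property
    def common(self) -> set[str]:
        return self.fst_outliers & self.cda_selected


@dataclass
class CandidateSet:
    """Main-contrast common markers minus pairwise-flagged exclusions."""

    common: set[str]
    exclusions: pd.DataFrame  # snp_id, contrast, method
    final: set[str]

    @property
    def excluded(self) -> set[str]:
        return self.common - self.final


@dataclass
class StudyReport:
    main: ComparisonResult
    pairwise: list[ComparisonResult]
    candidates: CandidateSet
    cda_candidates_only: CdaResult | None
    augmentation_sda: SdaResult | None
    augmentation_cda: CdaResult | None
    n_comparisons: int = 0

    def summary(self) -> dict:
        out = {
            "n_comparisons": self.n_comparisons,
            "main_contrast": self.main.label,
            "n_fst_outliers": len(self.main.fst_outliers),
            "n_cda_selected": len(self.main.cda_selected),
            "n_common": len(self.candidates.common),
            "n_excluded": len(self.candidates.excluded),
            "n_final_candidates": len(self.candidates.final),
            "final_candidates": sorted(self.candidates.final),
            "pairwise": {
                c.label: {
                    "n_fst_outliers": len(c.fst_outliers),
                    "n_cda_selected": len(c.cda_selected),
                    "n_common": len(c.common),
                } for c in sorted(self.pairwise, key=lambda c: c.label)
            },
        }
        if self.cda_candidates_only is not None:
            r = self.cda_candidates_only
            out["cda_candidates_only"] = {
                "mahalanobis_d2": r.mahalanobis_d2,
                "hotelling_t2": r.hotelling_t2,
                "p_value": r.p_value,
                "assignment_error": r.assignment_error,
            }
        if self.augmentation_cda is not None:
            r = self.augmentation_cda
            out["augmented"] = {
                "n_markers": int(len(r.variable_idx)),
                "mahalanobis_d2": r.mahalanobis_d2,
                "p_value": r.p_value,
                "assignment_error": r.assignment_error,
            }
        return out

    def write(self, out_dir: str | Path) -> None:
        """Write the study report as a directory of TSVs + summary JSON.

        Output is byte-deterministic for a given dataset + config: sets are
        sorted before writing and floats printed with a fixed format.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.main.fst_result.write_tsv(out / "main_fst_scan.tsv")
        pd.DataFrame({"snp_id": sorted(self.main.cda_selected)}).to_csv(
            out / "main_cda_selected.tsv", sep="\t", index=False)
        self.candidates.exclusions.to_csv(
            out / "exclusions.tsv", sep="\t", index=False)
        pd.DataFrame({"snp_id": sorted(self.candidates.final)}).to_csv(
            out / "final_candidates.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True,
                      default=float)
            fh.write("\n")


# ---------------------------------------------------------------------------

def run_comparison(ds: GenotypeDataset, popA_idx, popB_idx, label: str,
                   params: PipelineParams | None = None,
                   keep_details: bool = True) -> ComparisonResult:
    """Apply both branches to one contrast between two animal sets."""
    params = params or PipelineParams()
    popA_idx = np.asarray(popA_idx)
    popB_idx = np.asarray(popB_idx)
    if len(popA_idx) == 0 or len(popB_idx) == 0:
        raise ValueError("both populations must be non-empty")
    if set(popA_idx) & set(popB_idx):
        raise ValueError("populations must be disjoint")

    fst_res = fst_scan(ds, popA_idx, popB_idx, params.smooth, params.outlier)

    both = np.concatenate([popA_idx, popB_idx])
    both.sort()  # animal order must not depend on which side is A
    sub = ds.subset(animal_idx=both)
    in_a = set(int(i) for i in popA_idx)
    side = np.array(["A" if int(i) in in_a else "B" for i in both], dtype=object)
    X = mean_impute(sub)
    sda_res = hierarchical_sda(sub, side, params.sda, X=X)
    snp_ids = ds.snps["snp_id"].to_numpy()
    cda_selected = {str(snp_ids[j]) for j in sda_res.selected}
    cda_res = None
    if sda_res.selected:
        cda_res = cda_fit(X, side, variable_idx=sda_res.selected)
    return ComparisonResult(
        label=label,
        fst_outliers=fst_res.outlier_snp_ids(),
        cda_selected=cda_selected,
        fst_result=fst_res if keep_details else None,
        sda_result=sda_res if keep_details else None,
        cda_result=cda_res if keep_details else None,
    )


def build_exclusion_set(pairwise: list[ComparisonResult],
                        mode: str = "union_both_methods") -> pd.DataFrame:
    """Collect pairwise-flagged SNPs with provenance (contrast, method).

    ``union_both_methods`` takes every SNP flagged by either branch of any
    pairwise contrast; ``common_only`` takes only SNPs in a pairwise
    common (both-branch) set.
    """
    if mode not in ("union_both_methods", "common_only"):
        raise ValueError("unknown exclusion mode")
    rows = []
    for comp in pairwise:
        if mode == "union_both_methods":
            for s in comp.fst_outliers:
                rows.append((s, comp.label, "fst"))
            for s in comp.cda_selected:
                rows.append((s, comp.label, "cda"))
        else:
            for s in comp.common:
                rows.append((s, comp.label, "both"))
    df = pd.DataFrame(rows, columns=["snp_id", "contrast", "method"])
    return df.sort_values(["snp_id", "contrast", "method"]).reset_index(drop=True)


def candidate_markers(main: ComparisonResult,
                      exclusions: pd.DataFrame) -> CandidateSet:
    """Final candidates = main common set minus pairwise-flagged SNPs."""
    common = main.common
    excl_ids = set(exclusions["snp_id"]) if len(exclusions) else set()
    final = common - excl_ids
    kept_excl = exclusions[exclusions["snp_id"].isin(common)].reset_index(drop=True) \
        if len(exclusions) else exclusions
    return CandidateSet(common=common, exclusions=kept_excl, final=final)


def run_full_study(ds: GenotypeDataset,
                   params: PipelineParams | None = None,
                   run_augmentation: bool = True) -> StudyReport:
    """Run the complete design on a two-group, multi-breed dataset.

    The main contrast is group vs group; every within-group breed pair is
    analysed the same way with the same thresholds; exclusions and final
    candidates are derived; then CDA is refitted on the candidates alone
    and once more with stepwise augmentation keeping them forced in.
    """
    params = params or PipelineParams()
    groups = ds.animals["group"].to_numpy()
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")

    gA = np.nonzero(groups == labels[0])[0]
    gB = np.nonzero(groups == labels[1])[0]
    main_label = f"{labels[0]}_vs_{labels[1]}"
    main = run_comparison(ds, gA, gB, main_label, params)

    pairwise: list[ComparisonResult] = []
    breeds = ds.animals["breed"].to_numpy()
    for glabel in labels:
        in_group = sorted(set(breeds[groups == glabel].tolist()))
        for b1, b2 in itertools.combinations(in_group, 2):
            i1 = np.nonzero(breeds == b1)[0]
            i2 = np.nonzero(breeds == b2)[0]
            pairwise.append(run_comparison(
                ds, i1, i2, f"{b1}_vs_{b2}", params, keep_details=False))

    exclusions = build_exclusion_set(pairwise, params.exclusion_mode)
    cands = candidate_markers(main, exclusions)

    snp_pos = {s: j for j, s in enumerate(ds.snps["snp_id"])}
    cand_idx = sorted(snp_pos[s] for s in cands.final)
    X = mean_impute(ds)
    cda_cand = None
    aug_sda = aug_cda = None
    if cand_idx:
        cda_cand = cda_fit(X, groups, variable_idx=cand_idx,
                           positive_group=params.positive_group)
        if run_augmentation:
            aug_sda, aug_cda = cda_refit_with_augmentation(
                ds, groups, cand_idx, params.sda, X=X,
                positive_group=params.positive_group)
    return StudyReport(
        main=main, pairwise=pairwise, candidates=cands,
        cda_candidates_only=cda_cand,
        augmentation_sda=aug_sda, augmentation_cda=aug_cda,
        n_comparisons=1 + len(pairwise),
    )
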