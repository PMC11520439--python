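"""Reference study designs and ready-made synthetic configurations.

``OSCC_COHORTS`` records the published multi-cohort OSCC compendium this
method was developed on: nine GEO microarray cohorts (five platforms,
three vendors) split into discovery / evaluation / external-validation
roles, plus the TCGA head-and-neck RNA-seq cohort used for prognosis.
The catalog is bookkeeping only — expression data are never downloaded
here — but it fixes the sample-size arithmetic (821 samples, 552 OSCC,
474 discovery split 379/95, 268 external validation) and provides the
template the synthetic generator's cohort-structure preset mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

from .simulate import PlantedPair, SurvivalConfig, SyntheticConfig

__all__ = [
    "CohortInfo",
    "OSCC_COHORTS",
    "COMMON_GENE_COUNT",
    "cohort_totals",
    "discovery_split_sizes",
    "small_synthetic_config",
    "recovery_synthetic_config",
    "prognostic_synthetic_config",
]

# Number of genes detected in common across all nine cohorts; pairing all
# of them unrestricted would give n(n-1)/2 ≈ 5.8e7 candidate pairs.
COMMON_GENE_COUNT = 10_762


@dataclass(frozen=True)
class CohortInfo:
    accession: str
    n_case: int
    n_control: int
    role: str  # discovery | evaluation | validation | prognosis
    platform: str

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


OSCC_COHORTS: tuple[CohortInfo, ...] = (
    CohortInfo("GSE84846", 99, 0, "discovery", "Agilent-014850 4x44K G4112F"),
    CohortInfo("GSE30784", 167, 62, "discovery", "Affymetrix HG-U133 Plus 2.0"),
    CohortInfo("GSE37991", 40, 40, "discovery", "Illumina HumanRef-8 v3.0"),
    CohortInfo("GSE85446", 66, 0, "discovery", "Agilent-014850 4x44K G4112F"),
    CohortInfo("GSE25099", 57, 22, "evaluation", "Affymetrix HuEx-1_0-st"),
    CohortInfo("GSE89923", 57, 33, "validation", "Affymetrix HG-U133 Plus 2.0"),
    CohortInfo("GSE31056", 23, 73, "validation", "Affymetrix HG-U133 Plus 2.0"),
    CohortInfo("GSE85195", 16, 34, "validation", "Agilent-014850 4x44K G4112F"),
    CohortInfo("GSE23558", 27, 5, "validation", "Agilent-014850 4x44K G4112F"),
)

TCGA_PROGNOSIS = CohortInfo("TCGA-HNSC", 546, 0, "prognosis", "RNA-seq")


def cohort_totals(role: str | None = None) -> dict[str, int]:
    """Sample bookkeeping over the nine expression cohorts.

    Returns totals overall or restricted to one role; the prognosis
    cohort is excluded (it has no case/control design).
    """
    cohorts = [c for c in OSCC_COHORTS if role is None or c.role == role]
    return {
        "n_samples": sum(c.n_total for c in cohorts),
        "n_case": sum(c.n_case for c in cohorts),
        "n_control": sum(c.n_control for c in cohorts),
    }


def discovery_split_sizes(fraction_train: float = 0.8) -> tuple[int, int]:
    """Train/test sizes of the discovery pool under the 80/20 split."""
    n = cohort_totals("discovery")["n_samples"]
    n_train = floor(fraction_train * n)
    return n_train, n - n_train


def small_synthetic_config(seed: int = 0) -> SyntheticConfig:
    """Small end-to-end study: runs the whole pipeline in well under a
    minute while exercising every stage, including survival."""
    return SyntheticConfig(
        n_cohorts=3,
        cases_per_cohort=30,
        controls_per_cohort=30,
        n_genes=60,
        n_pathways=6,
        genes_per_pathway=10,
        planted_pairs=(
            PlantedPair("G0001", "G0002", 0.9, 0.1),
            PlantedPair("G0003", "G0004", 0.9, 0.1),
            PlantedPair("G0011", "G0012", 0.1, 0.9),
            PlantedPair("G0013", "G0014", 0.9, 0.1),
            PlantedPair("G0021", "G0022", 0.9, 0.1),
        ),
        batch_shift_sd=2.0,
        sample_distortion="affine",
        survival=SurvivalConfig(
            baseline_rate=0.25,
            betas=(("G0001", "G0002", 2.0), ("G0011", "G0012", -2.0)),
            censor_time_max=12.0,
        ),
        seed=seed,
    )


def recovery_synthetic_config(seed: int = 0) -> SyntheticConfig:
    """Planted-pair recovery benchmark: 5 pairs reversed at 0.9 (cases)
    vs 0.1 (controls), 3 cohorts of 50+50 samples (150 per group pooled),
    strong per-cohort batch shifts."""
    return SyntheticConfig(
        n_cohorts=3,
        cases_per_cohort=50,
        controls_per_cohort=50,
        n_genes=120,
        n_pathways=6,
        genes_per_pathway=20,
        planted_pairs=(
            PlantedPair("G0001", "G0002", 0.9, 0.1),
            PlantedPair("G0003", "G0004", 0.9, 0.1),
            PlantedPair("G0021", "G0022", 0.1, 0.9),
            PlantedPair("G0041", "G0042", 0.9, 0.1),
            PlantedPair("G0061", "G0062", 0.9, 0.1),
        ),
        batch_shift_sd=2.0,
        sample_distortion="affine",
        survival=None,
        seed=seed,
    )


def prognostic_synthetic_config(seed: int = 0, censored: bool = True) -> SyntheticConfig:
    """Prognostic recovery benchmark: six survival-driving pairs with
    known coefficients ±1 on pair features that vary freely among cases
    (reversal rate 0.5 in both groups), plus six null pairs."""
    planted = tuple(
        PlantedPair(f"G{2 * i - 1:04d}", f"G{2 * i:04d}", 0.5, 0.5) for i in range(1, 13)
    )
    betas = tuple(
        (f"G{2 * i - 1:04d}", f"G{2 * i:04d}", 1.0 if i % 2 else -1.0) for i in range(1, 7)
    )
    return SyntheticConfig(
        n_cohorts=1,
        cases_per_cohort=400,
        controls_per_cohort=10,
        n_genes=40,
        n_pathways=2,
        genes_per_pathway=20,
        planted_pairs=planted,
        batch_shift_sd=0.0,
        sample_distortion="none",
        survival=SurvivalConfig(
            baseline_rate=0.1,
            betas=betas,
            censor_time_max=40.0 if censored else None,
        ),
        seed=seed,
    )
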