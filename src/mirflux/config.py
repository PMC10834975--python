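"""Analysis configuration and controlled vocabularies.

All thresholds used by the pipeline live in :class:`AnalysisConfig` so that a
run is fully described by one object.  The defaults are the study's cut-offs:
detection at more than five reads per (tissue, age) group, a minimum UMI sum
of 10 across the three replicates of a compartment, two-sided p < 0.05 with a
1.5-fold change where the fold criterion applies, anti-correlation at Pearson
r < -0.2, a 2-fold bound on the age change of the EV loading ratio, and 1000
permutations for the trafficking-network test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: Somatic tissues profiled by the study design this package models.
DEFAULT_TISSUES: tuple[str, ...] = ("Neu", "Int", "BWM", "Hyp", "Coel")

#: Whole-organism and extracellular-vesicle compartments (UMI libraries).
DEFAULT_COMPARTMENTS: tuple[str, ...] = ("Worm", "EV")

#: Adult ages: day 1 (young) and day 8 (aged, post-reproductive).
DEFAULT_AGES: tuple[str, ...] = ("D1", "D8")

#: Label for trafficking sources outside the modelled tissue set.
OTHER_SOURCE = "Other"

#: Valid scales of an ExpressionMatrix, in the order transforms produce them.
SCALES = ("raw_count", "tpm", "log2tpm", "qnorm_log2tpm", "relative_abundance")

#: Group-level detection rules for read-count libraries.
GROUP_RULES = ("mean", "any", "all")


class VocabularyError(ValueError):
    """A tissue/age/compartment label outside the configured vocabulary."""


@dataclass
class AnalysisConfig:
    """Thresholds and vocabulary for one analysis run.

    Parameters
    ----------
    detection_read_threshold:
        A miRNA is expressed in a read-count library group when its count
        exceeds this value (strict ``>``); default 5 reads.
    detection_umi_sum_threshold:
        A miRNA is expressed in a UMI compartment when the UMI sum across the
        group's replicates reaches this value (inclusive ``>=``); default 10.
    p_threshold:
        Two-sided p-value cut-off for differential expression; default 0.05.
    fc_threshold:
        Fold-change bound for the compartment-mode DE criterion
        (FC > 1.5 or < 1/1.5); default 1.5.
    pcc_threshold:
        Signed Pearson bound for miRNA-target anti-correlation; default -0.2.
    loading_fold_threshold:
        Fold bound on the D8/D1 change of the EV loading ratio that defines
        age-promoted / age-suppressed secretion; default 2 (strict).
    n_permutations:
        Number of network randomisations for the trafficking edge test.
    pseudocount:
        Added before log2 and before fold-change ratios; default 1.
    mrna_detection_threshold:
        A gene counts as expressed in a (tissue, age) when its mean
        (pre-normalised) expression exceeds this value; default 0.
    """

    detection_read_threshold: float = 5.0
    detection_umi_sum_threshold: float = 10.0
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    pcc_threshold: float = -0.2
    loading_fold_threshold: float = 2.0
    n_permutations: int = 1000
    rng_seed: int = 0
    pseudocount: float = 1.0
    mrna_detection_threshold: float = 0.0
    detection_group_rule: str = "mean"
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    ages: tuple[str, ...] = DEFAULT_AGES

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError(f"p_threshold must lie in (0, 1), got {self.p_threshold}")
        for name in ("fc_threshold", "loading_fold_threshold", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.detection_group_rule not in GROUP_RULES:
            raise ValueError(
                f"detection_group_rule must be one of {GROUP_RULES}, "
                f"got {self.detection_group_rule!r}"
            )
        self.tissues = tuple(self.tissues)
        self.compartments = tuple(self.compartments)
        self.ages = tuple(self.ages)
        if OTHER_SOURCE in self.tissues:
            raise ValueError(f"{OTHER_SOURCE!r} is reserved and cannot be a tissue label")

    # -- vocabulary ---------------------------------------------------------

    @property
    def locations(self) -> tuple[str, ...]:
        """All valid sample locations: tissues plus compartments."""
        return self.tissues + self.compartments

    def check_tissue(self, label: str) -> str:
        if label not in self.locations:
            raise VocabularyError(
                f"unknown tissue/compartment label {label!r}; "
                f"expected one of {self.locations}"
            )
        return label

    def check_age(self, label: str) -> str:
        if label not in self.ages:
            raise VocabularyError(
                f"unknown age label {label!r}; expected one of {self.ages}"
            )
        return label

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("tissues", "compartments", "ages"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
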