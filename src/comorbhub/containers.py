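"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids. Non-negative
        intensities or already log-scale values.
    sample_group
        Optional Series mapping sample id -> {"case", "control"}.
    survival
        Optional DataFrame indexed by sample id with columns
        ``time_days`` (float, > 0) and ``event`` (0 = censored, 1 = death).
    """

    values: pd.DataFrame
    sample_group: pd.Series | None = None
    survival: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            # duplicates are legal pre-collapse; flag only structural problems
            pass
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.sample_group is not None:
            missing = set(self.values.columns) - set(self.sample_group.index)
            if missing:
                raise ValueError(f"samples missing group labels: {sorted(missing)[:5]}")
            self.sample_group = self.sample_group.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if self.sample_group is None:
            raise ValueError("no sample_group annotation")
        return list(self.sample_group.index[self.sample_group == group])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(genes)], self.sample_group, self.survival
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        grp = self.sample_group.loc[samples] if self.sample_group is not None else None
        surv = None
        if self.survival is not None:
            surv = self.survival.reindex([s for s in samples if s in self.survival.index])
        return ExpressionMatrix(self.values[samples], grp, surv)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic study, used to score recovery."""

    planted_hubs: list[str]
    module_membership: dict[str, int]
    de_direction: dict[str, str]  # gene -> {"up", "down"}; absent = null
    mirna_targets: dict[str, list[str]]
    association_scores: dict[str, dict[str, float]]  # gene -> {relevance, pmid_count}
    below_threshold_decoys: list[str] = field(default_factory=list)
    shared_mirnas: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_hubs": self.planted_hubs,
            "module_membership": self.module_membership,
            "de_direction": self.de_direction,
            "mirna_targets": self.mirna_targets,
            "association_scores": self.association_scores,
            "below_threshold_decoys": self.below_threshold_decoys,
            "shared_mirnas": self.shared_mirnas,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            planted_hubs=list(d["planted_hubs"]),
            module_membership={k: int(v) for k, v in d["module_membership"].items()},
            de_direction=dict(d["de_direction"]),
            mirna_targets={k: list(v) for k, v in d["mirna_targets"].items()},
            association_scores=d["association_scores"],
            below_threshold_decoys=list(d.get("below_threshold_decoys", [])),
            shared_mirnas=list(d.get("shared_mirnas", [])),
        )
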