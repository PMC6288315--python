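"""Core containers shared by every analysis stage.

The pipeline operates on a feature-by-sample matrix of FPKM expression
values for two groups of animals (``H`` = high phenotype, ``L`` = low),
a BED-derived feature annotation, and a per-sample phenotype table
(intramuscular fat percentage, IMF).  Coordinates are 1-based inclusive
in memory; the on-disk BED convention (0-based half-open) is converted
at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("H", "L")
BIOTYPES = ("coding", "lncRNA", "TRF", "other")
STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file or value violates the expected exchange format."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (e.g. matrix and metadata) do not."""


@dataclass
class ExpressionMatrix:
    """FPKM values for features x samples plus H/L group labels.

    Parameters
    ----------
    values
        DataFrame of non-negative finite FPKM values, rows indexed by
        feature id, columns by sample id.
    groups
        Series mapping every sample id to ``"H"`` or ``"L"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise FormatError("duplicate feature ids in expression matrix")
        if v.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric values in expression matrix")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at feature {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative FPKM at feature {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        missing = v.columns.difference(self.groups.index)
        if len(missing):
            raise ConsistencyError(f"samples without group label: {list(missing)}")
        self.groups = self.groups.reindex(v.columns)
        bad_groups = set(self.groups.unique()) - set(GROUPS)
        if bad_groups:
            raise FormatError(f"unknown group labels: {sorted(bad_groups)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples belonging to one group."""
        return self.values[self.samples_in_group(group)]

    def require_min_group_size(self, n: int = 2) -> None:
        for g in GROUPS:
            if len(self.samples_in_group(g)) < n:
                raise ConsistencyError(
                    f"group {g!r} has fewer than {n} samples"
                )

    def subset(self, feature_ids) -> "ExpressionMatrix":
        missing = pd.Index(feature_ids).difference(self.values.index)
        if len(missing):
            raise ConsistencyError(f"features not in matrix: {list(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[feature_ids], self.groups)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a feature annotation table (1-based inclusive coordinates).

    Expected columns: chrom, start, end, strand, biotype; index = feature id.
    """
    if ann.index.has_duplicates:
        raise FormatError("duplicate feature ids in annotation")
    for col in ("chrom", "start", "end", "strand", "biotype"):
        if col not in ann.columns:
            raise FormatError(f"annotation missing column {col!r}")
    if len(ann) == 0:
        return ann
    if (ann["start"] > ann["end"]).any():
        bad = ann.index[ann["start"] > ann["end"]][0]
        raise FormatError(f"start > end for feature {bad!r}")
    bad_bt = set(ann["biotype"].unique()) - set(BIOTYPES)
    if bad_bt:
        raise FormatError(f"unknown biotype(s): {sorted(bad_bt)}")
    bad_st = set(ann["strand"].unique()) - set(STRANDS)
    if bad_st:
        raise FormatError(f"unknown strand(s): {sorted(bad_st)}")
    return ann


def validate_phenotype(pheno: pd.DataFrame,
                       matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Validate a phenotype table (index = sample id, columns imf, group)."""
    if "imf" not in pheno.columns or "group" not in pheno.columns:
        raise FormatError("phenotype table needs columns 'imf' and 'group'")
    imf = pheno["imf"].dropna()
    if (imf <= 0).any():
        raise FormatError("IMF values must be positive")
    if matrix is not None:
        if set(pheno.index) != set(matrix.sample_ids):
            raise ConsistencyError("phenotype samples differ from matrix samples")
    return pheno


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic-data generator.

    Used as the oracle in recovery tests: which features carry a real
    group effect, which TRFs are wired as regulators, module membership,
    planted hubs, per-module latent factors and trait correlations, and
    the designated cis lncRNA-gene partners.
    """

    de_log2fc: dict[str, float] = field(default_factory=dict)
    regulator_trfs: set[str] = field(default_factory=set)
    module_assignment: dict[str, str] = field(default_factory=dict)
    hub_features: set[str] = field(default_factory=set)
    phenotype_model: dict[str, float] = field(default_factory=dict)
    module_factors: dict[str, np.ndarray] = field(default_factory=dict)
    cis_partners: dict[str, str] = field(default_factory=dict)

    @property
    def de_features(self) -> set[str]:
        return set(self.de_log2fc)

    def to_jsonable(self) -> dict:
        return {
            "de_log2fc": self.de_log2fc,
            "regulator_trfs": sorted(self.regulator_trfs),
            "module_assignment": self.module_assignment,
            "hub_features": sorted(self.hub_features),
            "phenotype_model": self.phenotype_model,
            "module_factors": {k: list(map(float, v))
                               for k, v in self.module_factors.items()},
            "cis_partners": self.cis_partners,
        }
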