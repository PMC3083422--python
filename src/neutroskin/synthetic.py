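"""Synthetic data generators with planted ground truth.

The generators emulate the three data streams of a dose/time-course skin
irradiation study — two-channel 28,000-probe expression arrays, per-mouse
duplicate-Ct qPCR tables with a housekeeping reference, and per-mouse
multi-area densitometry — with known (planted) effects so that every
downstream step can be validated by recovery tests.

The default study design is four irradiated conditions (0.2 Gy and 1 Gy,
sampled at 6 h and 24 h) against a sham-irradiated calibrator, two replicate
hybridizations per condition, and four mice per group.  The default planted
expression structure mirrors the biology the analysis is built to detect:
a 40-gene keratin-like block induced at the low dose/early time and mildly
repressed at the high dose, and a 10-gene S100-like block induced at the low
dose at both times; all remaining genes are null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "PlantedEffects",
    "NoiseModel",
    "generate_microarrays",
    "generate_qpcr",
    "generate_densitometry",
    "write_arrays",
    "write_ground_truth",
]

SHAM_GROUP = "sham"


def condition_label(dose: float, time_h: float) -> str:
    dose_s = f"{dose:g}".replace(".", "p")
    return f"{dose_s}Gy_{time_h:g}h"


@dataclass(frozen=True)
class StudyDesign:
    """Experimental layout of the irradiation study."""

    n_genes: int = 28000
    conditions: tuple[tuple[float, float], ...] = ((0.2, 6.0), (0.2, 24.0), (1.0, 6.0), (1.0, 24.0))
    replicates_per_condition: int = 2
    mice_per_group: int = 4

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates_per_condition < 1 or self.mice_per_group < 1:
            raise ValueError("design counts must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")

    @property
    def condition_labels(self) -> list[str]:
        return [condition_label(d, t) for d, t in self.conditions]

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass(frozen=True)
class PlantedEffects:
    """True log2 fold changes per gene × condition, with named blocks.

    Block members share the block profile exactly before noise is added.
    """

    log2fc: pd.DataFrame  # genes × condition labels
    blocks: Mapping[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.blocks.items():
            block = self.log2fc.loc[members]
            if not (block.nunique(axis=0) <= 1).all():
                raise ValueError(f"block {name!r} members do not share a single profile")

    @classmethod
    def default(cls, design: StudyDesign) -> "PlantedEffects":
        """Keratin-like (40 genes) + S100-like (10 genes) blocks, rest null."""
        labels = design.condition_labels
        genes = design.gene_ids
        fc = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=labels)
        profiles = {
            # induced early at the low dose, mildly repressed at the high dose
            "keratin_like": {labels[0]: 1.2, labels[1]: 0.0, labels[2]: -0.4, labels[3]: -0.4},
            # induced at the low dose at both sampling times
            "s100_like": {labels[0]: 1.0, labels[1]: 1.0, labels[2]: 0.0, labels[3]: 0.0},
        }
        sizes = {"keratin_like": 40, "s100_like": 10}
        blocks: dict[str, list[str]] = {}
        start = 0
        for name, size in sizes.items():
            if start + size > len(genes):
                raise ValueError("design has fewer genes than the default planted blocks")
            members = genes[start : start + size]
            blocks[name] = members
            for cond, value in profiles[name].items():
                fc.loc[members, cond] = value
            start += size
        return cls(log2fc=fc, blocks=blocks)

    def truth_table(self) -> pd.DataFrame:
        """Long (gene, condition, true_log2fc) table for sidecar export."""
        long = self.log2fc.stack().rename("true_log2fc").reset_index()
        long.columns = ["gene_id", "condition", "true_log2fc"]
        return long


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description shared by the generators.

    ``dye_bias_coeffs`` are ascending polynomial coefficients of the
    intensity-dependent dye bias evaluated at (A - 10), A being the mean
    log2 intensity; the default is a visibly curved cubic of a few tenths of
    a log2 unit, typical of uncorrected two-channel arrays.
    """

    spot_sd: float = 0.1
    dye_bias_coeffs: tuple[float, ...] = (0.3, -0.1, 0.02, 0.01)
    flag_rate: float = 0.02
    saturation_level: float = 65535.0
    low_signal_rate: float = 0.01
    ct_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.flag_rate, self.low_signal_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rates must be in [0, 1], got {rate}")
        if self.spot_sd < 0 or self.ct_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def dye_bias(self, a: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(a) - 10.0, self.dye_bias_coeffs)


# ---------------------------------------------------------------------------
# microarrays


def generate_microarrays(
    design: StudyDesign,
    effects: PlantedEffects,
    noise: NoiseModel,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Simulate one two-channel array per condition × replicate.

    Per spot the mean log2 intensity A is log-normal (log2-mean 10, log2-SD
    1.5); the measured log-ratio is the planted log2 fold change plus the
    intensity-dependent dye bias plus N(0, spot_sd) noise.  Channel
    foregrounds are reconstructed from (A, M), clipped at the saturation
    level; a ``flag_rate`` fraction of spots is flagged bad (-50) and a
    ``low_signal_rate`` fraction collapsed into the background.

    Returns a mapping (condition_label, replicate_index) -> spot table with
    columns spot_id, gene_id, F_sample, B_sample, F_ref, B_ref, flag.
    """
    if list(effects.log2fc.index) != design.gene_ids:
        raise ValueError("effects.log2fc index does not match the design gene list")
    if list(effects.log2fc.columns) != design.condition_labels:
        raise ValueError("effects.log2fc columns do not match the design conditions")
    rng = np.random.default_rng(noise.seed)
    n = design.n_genes
    spot_ids = [f"spot_{i:05d}" for i in range(1, n + 1)]
    arrays: dict[tuple[str, int], pd.DataFrame] = {}
    for cond in design.condition_labels:
        planted = effects.log2fc[cond].to_numpy()
        for rep in range(1, design.replicates_per_condition + 1):
            a = rng.normal(10.0, 1.5, size=n)
            m = planted + noise.dye_bias(a) + rng.normal(0.0, noise.spot_sd, size=n)
            f_sample = np.minimum(2.0 ** (a + m / 2.0), noise.saturation_level)
            f_ref = np.minimum(2.0 ** (a - m / 2.0), noise.saturation_level)
            b_sample = np.abs(rng.normal(100.0, 10.0, size=n))
            b_ref = np.abs(rng.normal(100.0, 10.0, size=n))
            flags = np.zeros(n, dtype=int)
            flags[rng.random(n) < noise.flag_rate] = -50
            low = rng.random(n) < noise.low_signal_rate
            f_sample[low] = b_sample[low] * np.abs(rng.normal(1.0, 0.05, size=int(low.sum())))
            f_ref[low] = b_ref[low] * np.abs(rng.normal(1.0, 0.05, size=int(low.sum())))
            arrays[(cond, rep)] = pd.DataFrame(
                {
                    "spot_id": spot_ids,
                    "gene_id": design.gene_ids,
                    "F_sample": f_sample,
                    "B_sample": b_sample,
                    "F_ref": f_ref,
                    "B_ref": b_ref,
                    "flag": flags,
                }
            )
    return arrays


# ---------------------------------------------------------------------------
# qPCR


def generate_qpcr(
    design: StudyDesign,
    genes: Sequence[str],
    planted_log2fc: pd.DataFrame,
    noise: NoiseModel,
    reference_gene: str = "Gapdh",
) -> pd.DataFrame:
    """Simulate a long-format duplicate-Ct table.

    Groups are the sham calibrator plus the design conditions; the
    calibrator must be present in ``planted_log2fc`` columns with planted
    log2fc 0.  The reference (housekeeping) gene cycles at Ct ~ 20; each
    target gene sits at a fixed offset from it, shifted down by the planted
    log2 fold change (amplification efficiency exactly 2), and every
    reaction is measured as two technical duplicates with N(0, ct_sd) error.

    Returns columns mouse_id, group, gene, ct_rep1, ct_rep2.
    """
    groups = [SHAM_GROUP] + design.condition_labels
    if SHAM_GROUP not in planted_log2fc.columns:
        raise ValueError(f"planted_log2fc must contain the calibrator group {SHAM_GROUP!r}")
    if not np.allclose(planted_log2fc[SHAM_GROUP], 0.0):
        raise ValueError("calibrator-group planted log2fc must be 0")
    rng = np.random.default_rng(noise.seed + 1)
    offsets = {g: rng.uniform(2.0, 8.0) for g in genes}
    rows = []
    for group in groups:
        for mouse_i in range(1, design.mice_per_group + 1):
            mouse = f"{group}_m{mouse_i}"
            ref_base = 20.0
            rows.append(
                (mouse, group, reference_gene,
                 ref_base + rng.normal(0.0, noise.ct_sd),
                 ref_base + rng.normal(0.0, noise.ct_sd))
            )
            for gene in genes:
                base = ref_base + offsets[gene] - float(planted_log2fc.loc[gene, group])
                rows.append(
                    (mouse, group, gene,
                     base + rng.normal(0.0, noise.ct_sd),
                     base + rng.normal(0.0, noise.ct_sd))
                )
    return pd.DataFrame(rows, columns=["mouse_id", "group", "gene", "ct_rep1", "ct_rep2"])


# ---------------------------------------------------------------------------
# densitometry


def generate_densitometry(
    group_medians: Mapping[str, float],
    spread: float,
    design: StudyDesign,
    outlier_rate: float = 0.0,
    seed: int = 0,
    areas_per_mouse: int = 4,
    background_level: float = 10.0,
) -> pd.DataFrame:
    """Simulate per-mouse, per-area optical-density scores.

    Each group contributes ``mice_per_group`` mice with ``areas_per_mouse``
    scored areas; values are Normal(group median, spread) with occasional
    3x-shifted outliers at ``outlier_rate``.  A background staining channel
    (Normal(background_level, spread/4)) is included for normalization.

    Returns columns mouse_id, group, area, density, background.
    """
    if spread < 0:
        raise ValueError("spread must be >= 0")
    if not (0.0 <= outlier_rate <= 1.0):
        raise ValueError("outlier_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for group, median in group_medians.items():
        for mouse_i in range(1, design.mice_per_group + 1):
            mouse = f"{group}_m{mouse_i}"
            for area in range(1, areas_per_mouse + 1):
                value = rng.normal(median, spread)
                if rng.random() < outlier_rate:
                    value *= 3.0
                background = rng.normal(background_level, spread / 4.0)
                rows.append((mouse, group, area, value, background))
    return pd.DataFrame(rows, columns=["mouse_id", "group", "area", "density", "background"])


# ---------------------------------------------------------------------------
# writers (dialects consumed by the downstream readers)


def write_arrays(
    arrays: Mapping[tuple[str, int], pd.DataFrame],
    outdir: str | Path,
    header_comment: str | None = None,
) -> list[Path]:
    """Write each array as `<condition>_rep<r>.tsv` in GenePix-like TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (cond, rep), table in arrays.items():
        path = outdir / f"{cond}_rep{rep}.tsv"
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            table.to_csv(fh, sep="\t", index=False)
        paths.append(path)
    return paths


def write_ground_truth(effects: PlantedEffects, path: str | Path) -> None:
    effects.truth_table().to_csv(path, sep="\t", index=False)
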