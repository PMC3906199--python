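"""Synthetic abiotic-stress expression datasets with known ground truth.

The generator emulates a four-stress (cold, drought, heat, salt) time-course
microarray experiment on the RMA log2 scale: five sampling times (1, 2, 5,
10, 24 h), biological triplicates, a matched control series, and a single
dropped stress array (heat, 5 h, replicate C) mirroring a quality-control
failure.  Genes are organised into latent co-expression modules with
stress-specific response profiles, a subset of transcription-factor (TF)
genes, planted "plastic" TF-target pairs whose correlation flips sign
between two conditions, and promoters with planted short motifs.

Every quantity needed to score a downstream analysis (module labels, true
response profiles, plastic pairs, motif placements) is recorded in a
:class:`GroundTruth` object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

STRESSES = ("cold", "drought", "heat", "salt")
TIMEPOINTS_H = (1, 2, 5, 10, 24)
REPLICATES = ("A", "B", "C")
CONTROL = "control"

_ALPHABET = "ACGT"


def _default_module_sizes(n_genes: int, n_modules: int) -> list[int]:
    """Distribute ~2/3 of the genes over modules with a decaying size profile.

    Mirrors the observed pattern where module sizes fall off steeply from the
    largest module and the smallest modules sit at the minimum size (25).
    """
    if n_modules == 0:
        return []
    budget = int(round(n_genes * 0.67))
    # geometric decay, floor at 25
    raw = np.power(0.82, np.arange(n_modules))
    sizes = np.maximum(np.round(budget * raw / raw.sum()).astype(int), 25)
    # trim overshoot from the largest modules
    while sizes.sum() > min(budget, n_genes) and sizes.max() > 25:
        sizes[int(np.argmax(sizes))] -= 1
    return sizes.tolist()


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the structure of the emulated experiment at desk
    scale: 4 stresses x 5 timepoints x 3 replicates plus matched controls,
    one missing heat array, RMA baselines centred near 8 with SD 2, planted
    differential-expression effects of at least one RMA unit, and ~6% of
    genes flagged as transcription factors.
    """

    n_genes: int = 2000
    n_modules: int = 22
    module_sizes: list[int] | None = None
    stresses: tuple[str, ...] = STRESSES
    timepoints_h: tuple[int, ...] = TIMEPOINTS_H
    n_replicates: int = 3
    de_effect_rma: float = 1.5
    noise_sd_rma: float = 0.3
    module_latent_sd_rma: float = 0.2  # shared per-array co-fluctuation within a module
    baseline_mean_rma: float = 8.0
    baseline_sd_rma: float = 2.0
    n_tfs: int | None = None
    n_plastic_pairs: int = 20
    plastic_conditions: tuple[str, str] = ("drought", "salt")
    plastic_amplitude_rma: float = 1.0
    promoter_length_nt: int = 500
    planted_motifs: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("CAACGGTC", 1, 0.6)]
    )
    dropouts: list[tuple[str, int, str]] = field(
        default_factory=lambda: [("heat", 5, "C")]
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = _default_module_sizes(self.n_genes, self.n_modules)
        else:
            self.n_modules = len(self.module_sizes)
        if self.n_tfs is None:
            self.n_tfs = int(round(0.06 * self.n_genes))
        self.validate()

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs exceeds n_genes")
        if list(self.timepoints_h) != sorted(set(self.timepoints_h)):
            raise ValueError("timepoints_h must be strictly increasing")
        seen: set[tuple[str, int]] = set()
        for motif, module, rate in self.planted_motifs:
            if not set(motif) <= set(_ALPHABET):
                raise ValueError(f"motif {motif!r} contains non-ACGT characters")
            if not 5 <= len(motif) <= 8:
                raise ValueError(f"motif {motif!r} must be 5-8 nt long")
            if not 0 < rate <= 1:
                raise ValueError(f"planting rate {rate} not in (0, 1]")
            if len(motif) > self.promoter_length_nt:
                raise ValueError("promoter_length_nt shorter than planted motif")
            if (motif, module) in seen:
                raise ValueError(f"duplicate planting of {motif!r} in module {module}")
            seen.add((motif, module))


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    module_labels: pd.Series  # gene -> module (0 = none)
    module_profiles: pd.DataFrame  # rows: module; columns: (stress, hour) -> delta RMA
    tf_genes: list[str]
    plastic_pairs: pd.DataFrame  # tf, tg, condition_a, condition_b, r_a_true, r_b_true
    motif_placements: pd.DataFrame  # gene, motif, offset (filled by generate_promoters)
    seed: int


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def make_design(config: SyntheticConfig) -> pd.DataFrame:
    """Sample sheet: one row per array, controls matched at every timepoint."""
    rows = []
    reps = REPLICATES[: config.n_replicates]
    dropped = set(config.dropouts)
    for cond in list(config.stresses) + [CONTROL]:
        for t in config.timepoints_h:
            for rep in reps:
                if (cond, t, rep) in dropped:
                    continue
                rows.append(
                    {
                        "sample_id": f"{cond}_{t:02d}h_{rep}",
                        "condition": cond,
                        "timepoint_h": t,
                        "replicate": rep,
                        "is_control": cond == CONTROL,
                    }
                )
    return pd.DataFrame(rows)


def _module_profile_table(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign each module a stress-response profile (delta RMA per stress/hour).

    Each module responds to one primary stress (cycled so all stresses are
    covered) with amplitude ``de_effect_rma`` ramping over the time course;
    most modules additionally respond to drought at half amplitude, echoing
    the drought-dominated modular response of the emulated study.
    """
    cols = pd.MultiIndex.from_product(
        [config.stresses, config.timepoints_h], names=["stress", "timepoint_h"]
    )
    # rapid onset followed by a slow build to the full effect at the last
    # sampling time: responses are already strong at the first hour
    ramp = np.asarray(config.timepoints_h, dtype=float)
    ramp = 0.7 + 0.3 * ramp / ramp.max()
    profiles = pd.DataFrame(
        0.0, index=range(1, config.n_modules + 1), columns=cols
    )
    for m in profiles.index:
        primary = config.stresses[(m - 1) % len(config.stresses)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        profiles.loc[m, (primary, slice(None))] = sign * config.de_effect_rma * ramp
        if primary != "drought" and "drought" in config.stresses and rng.random() < 0.7:
            profiles.loc[m, ("drought", slice(None))] = (
                sign * 0.5 * config.de_effect_rma * ramp
            )
    return profiles


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression matrix, sample design, ground truth).

    Returns
    -------
    matrix : DataFrame, genes x arrays, RMA-scale values.
    design : DataFrame with sample_id/condition/timepoint_h/replicate/is_control.
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.rng_seed)
    design = make_design(config)
    genes = _gene_ids(config.n_genes)

    if config.n_genes == 0:
        empty = pd.DataFrame(index=[], columns=design["sample_id"], dtype=float)
        truth = GroundTruth(
            module_labels=pd.Series(dtype=int),
            module_profiles=pd.DataFrame(),
            tf_genes=[],
            plastic_pairs=pd.DataFrame(
                columns=["tf", "tg", "condition_a", "condition_b", "r_a_true", "r_b_true"]
            ),
            motif_placements=pd.DataFrame(columns=["gene", "motif", "offset"]),
            seed=config.rng_seed,
        )
        return empty, design, truth

    labels = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[pos : pos + size] = m
        pos += size
    module_labels = pd.Series(labels, index=genes, name="module")

    profiles = _module_profile_table(config, rng)

    # TFs drawn preferentially from outside modules (matching the observed
    # depletion of TF loci from co-expression modules)
    non_module = np.where(labels == 0)[0]
    n_tf_out = min(len(non_module), int(round(config.n_tfs * 0.8)))
    tf_idx = list(rng.choice(non_module, size=n_tf_out, replace=False))
    remaining = config.n_tfs - n_tf_out
    if remaining > 0:
        pool = np.setdiff1d(np.arange(config.n_genes), np.asarray(tf_idx, dtype=int))
        tf_idx += list(rng.choice(pool, size=remaining, replace=False))
    tf_idx = sorted(int(i) for i in tf_idx)
    tf_genes = [genes[i] for i in tf_idx]

    baseline = rng.normal(config.baseline_mean_rma, config.baseline_sd_rma, config.n_genes)
    loading = rng.uniform(0.8, 1.2, config.n_genes)

    n_arrays = len(design)
    X = np.empty((config.n_genes, n_arrays))
    cond = design["condition"].to_numpy()
    hour = design["timepoint_h"].to_numpy()
    # biological co-fluctuation shared by module members within each array
    latent = rng.normal(0.0, config.module_latent_sd_rma, (config.n_modules, n_arrays))
    for j in range(n_arrays):
        mu = np.full(config.n_genes, 0.0)
        for m in profiles.index:
            delta = profiles.loc[m, (cond[j], hour[j])] if cond[j] != CONTROL else 0.0
            mu[labels == m] = delta + latent[m - 1, j]
        X[:, j] = baseline + loading * mu
    X += rng.normal(0.0, config.noise_sd_rma, X.shape)

    # plastic TF-target pairs: a shared latent driver per pair, mixed with a
    # sign flip in the second condition so the pair correlation reverses.
    cond_a, cond_b = config.plastic_conditions
    cols_a = np.where(cond == cond_a)[0]
    cols_b = np.where(cond == cond_b)[0]
    pair_rows = []
    if config.n_plastic_pairs > 0 and len(cols_a) >= 3 and len(cols_b) >= 3:
        # reserve distinct non-module, non-TF genes as targets; TFs from TF pool
        tf_pool = [i for i in tf_idx if labels[i] == 0]
        tg_pool = [i for i in non_module if i not in set(tf_idx)]
        n_pairs = min(config.n_plastic_pairs, len(tf_pool), len(tg_pool))
        tf_sel = rng.choice(tf_pool, size=n_pairs, replace=False)
        tg_sel = rng.choice(tg_pool, size=n_pairs, replace=False)
        c = config.plastic_amplitude_rma
        r_true = c * c / (c * c + config.noise_sd_rma**2)
        for tf_i, tg_i in zip(tf_sel, tg_sel):
            z_a = rng.standard_normal(len(cols_a))
            z_b = rng.standard_normal(len(cols_b))
            X[tf_i, cols_a] += c * z_a
            X[tf_i, cols_b] += c * z_b
            X[tg_i, cols_a] += c * z_a
            X[tg_i, cols_b] -= c * z_b
            # flat DE shift under both conditions keeps the pair in the
            # DE-in-both universe without adding shared time structure
            X[tf_i, cols_a] += config.de_effect_rma
            X[tf_i, cols_b] += config.de_effect_rma
            X[tg_i, cols_a] += config.de_effect_rma
            X[tg_i, cols_b] += config.de_effect_rma
            pair_rows.append(
                {
                    "tf": genes[tf_i],
                    "tg": genes[tg_i],
                    "condition_a": cond_a,
                    "condition_b": cond_b,
                    "r_a_true": r_true,
                    "r_b_true": -r_true,
                }
            )

    matrix = pd.DataFrame(X, index=genes, columns=design["sample_id"].to_list())
    truth = GroundTruth(
        module_labels=module_labels,
        module_profiles=profiles,
        tf_genes=tf_genes,
        plastic_pairs=pd.DataFrame(
            pair_rows,
            columns=["tf", "tg", "condition_a", "condition_b", "r_a_true", "r_b_true"],
        ),
        motif_placements=pd.DataFrame(columns=["gene", "motif", "offset"]),
        seed=config.rng_seed,
    )
    return matrix, design, truth


def generate_promoters(
    config: SyntheticConfig, truth: GroundTruth
) -> dict[str, str]:
    """Uniform-background promoters with motifs planted in target modules.

    Returns a gene -> sequence mapping (uppercase ACGT, length
    ``promoter_length_nt``).  Placement offsets are appended to
    ``truth.motif_placements``.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    genes = list(truth.module_labels.index)
    n = len(genes)
    L = config.promoter_length_nt
    seqs = rng.integers(0, 4, size=(n, L), dtype=np.int8)
    placements = []
    labels = truth.module_labels
    lut = {c: i for i, c in enumerate(_ALPHABET)}
    for motif, module, rate in config.planted_motifs:
        targets = [g for g in genes if labels[g] == module]
        n_plant = int(round(rate * len(targets)))
        chosen = rng.choice(len(targets), size=n_plant, replace=False)
        enc = np.array([lut[c] for c in motif], dtype=np.int8)
        for ti in chosen:
            g = targets[int(ti)]
            gi = genes.index(g)
            offset = int(rng.integers(0, L - len(motif) + 1))
            seqs[gi, offset : offset + len(motif)] = enc
            placements.append({"gene": g, "motif": motif, "offset": offset})
    arr = np.frombuffer(bytes(_ALPHABET, "ascii"), dtype=np.uint8)[seqs]
    out = {g: arr[i].tobytes().decode("ascii") for i, g in enumerate(genes)}
    truth.motif_placements = pd.concat(
        [truth.motif_placements, pd.DataFrame(placements, columns=["gene", "motif", "offset"])],
        ignore_index=True,
    )
    return out


def generate_annotations(
    config: SyntheticConfig, truth: GroundTruth
) -> dict[str, object]:
    """TF list, a non-modular gene class, and a term -> genes map.

    The non-modular class emulates gene families (e.g. calcium-binding loci)
    that respond to stress individually rather than through modules: 80% of
    the class is drawn from outside modules.  One term is planted covering
    exactly module 1 so term enrichment has a known positive control.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    labels = truth.module_labels
    genes = list(labels.index)
    non_module = [g for g in genes if labels[g] == 0]
    in_module = [g for g in genes if labels[g] != 0]
    class_size = min(max(len(genes) // 20, 1), len(genes))
    n_out = min(int(round(class_size * 0.8)), len(non_module))
    cls = list(rng.choice(non_module, size=n_out, replace=False))
    if class_size - n_out > 0 and in_module:
        cls += list(rng.choice(in_module, size=min(class_size - n_out, len(in_module)), replace=False))
    term_map: dict[str, list[str]] = {}
    if (labels == 1).any():
        term_map["TERM:module1"] = [g for g in genes if labels[g] == 1]
    if non_module:
        k = min(50, len(non_module))
        term_map["TERM:scatter"] = sorted(rng.choice(non_module, size=k, replace=False))
    return {
        "tf_genes": list(truth.tf_genes),
        "nonmodular_class": sorted(cls),
        "term_map": term_map,
    }


def write_bundle(
    outdir: str | Path,
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    truth: GroundTruth,
    promoters: dict[str, str] | None = None,
    annotations: dict[str, object] | None = None,
) -> None:
    """Write the fixture bundle as plain-text TSV/FASTA files plus a seed sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    truth.module_labels.rename("module").to_csv(
        outdir / "truth_modules.tsv", sep="\t", index_label="gene"
    )
    truth.plastic_pairs.to_csv(outdir / "truth_plastic_pairs.tsv", sep="\t", index=False)
    truth.motif_placements.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)
    if promoters is not None:
        with open(outdir / "promoters.fasta", "w") as fh:
            for g, seq in promoters.items():
                fh.write(f">{g}\n{seq}\n")
    if annotations is not None:
        with open(outdir / "tf_genes.txt", "w") as fh:
            fh.write("\n".join(annotations["tf_genes"]) + "\n")
        with open(outdir / "nonmodular_class.txt", "w") as fh:
            fh.write("\n".join(annotations["nonmodular_class"]) + "\n")
        with open(outdir / "term_map.json", "w") as fh:
            json.dump(annotations["term_map"], fh, indent=1)
    with open(outdir / "seed.json", "w") as fh:
        json.dump({"rng_seed": truth.seed}, fh)
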