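"""Seeded synthetic three-omics datasets with planted class structure.

The generator emulates the shape of a TCGA-style tumor-grade study: three
aligned omic matrices (expression, methylation, CNA) over the same genes
and samples, ~hundreds of samples in 3 classes, a small set of signal
genes whose per-omic means shift with the class, and a much larger raw
gene set padded with near-constant rows and non-approved symbols to
exercise the preprocessing filters.  One omic drops a small fraction of
samples so the complete-case sample intersection is always exercised.

It does not attempt to model real CNA discreteness, methylation
beta-value distributions, or batch structure: values are truncated
Gaussians on a [0, 1] scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_preprocess import FeatureMatrix, MultiOmicsDataset, OmicKind, ValidationError

OMICS = ("expression", "methylation", "cna")

# Recurrently mutated prostate-adenocarcinoma genes; used as the planted
# signal-gene symbols so fixtures read like real data.
_SIGNAL_SYMBOLS = [
    "SPOP", "TP53", "PTEN", "FOXA1", "MED12", "ATM", "KMT2C",
    "KMT2D", "AR", "ZFHX3", "CDK12", "ERF", "AKT1", "BRAF",
    "IDH1", "SMAD4", "RB1", "APC", "CTNNB1", "PIK3CA",
]


@dataclass
class SyntheticSpec:
    """Study conditions for one generated dataset.

    Defaults emulate the shape of the prostate-adenocarcinoma study the
    pipeline targets: 387 complete-case samples, 3 Gleason-group classes,
    14 selected genes out of a 2000-gene raw table.  ``effect_size`` is
    the between-adjacent-class mean shift per signal gene per omic on the
    [0, 1] scale; ``noise_sd`` the within-class standard deviation.
    """

    n_samples: int = 387
    n_genes_raw: int = 2000
    n_genes_signal: int = 14
    n_classes: int = 3
    class_proportions: tuple[float, ...] | None = None
    effect_size: float = 0.2
    noise_sd: float = 0.08
    frac_low_variance: float = 0.10
    frac_bad_symbols: float = 0.05
    missing_sample_frac: float = 0.05
    low_variance_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_proportions is None:
            self.class_proportions = tuple([1.0 / self.n_classes] * self.n_classes)
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape[0] != self.n_classes or not np.isclose(props.sum(), 1.0):
            raise ValidationError("class_proportions must sum to 1 over n_classes entries")
        if self.n_genes_signal > self.n_genes_raw:
            raise ValidationError("n_genes_signal exceeds n_genes_raw")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValidationError("effect_size must be >= 0 and noise_sd > 0")
        n_special = (
            self.n_genes_signal
            + round(self.frac_low_variance * self.n_genes_raw)
            + round(self.frac_bad_symbols * self.n_genes_raw)
        )
        if self.frac_low_variance + self.frac_bad_symbols > 1 or n_special > self.n_genes_raw:
            raise ValidationError("low-variance + bad-symbol fractions are infeasible")


@dataclass
class GeneratedData:
    """Raw tables, labels and the ground truth behind them."""

    expression: FeatureMatrix
    methylation: FeatureMatrix
    cna: FeatureMatrix
    labels: dict[str, int]
    class_names: list[str]
    gene_list: list[str]           # the planted signal genes
    approved_symbols: list[str]    # the HUGO stand-in list
    ground_truth: dict

    def matrix(self, omic: str) -> FeatureMatrix:
        return getattr(self, omic)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit TSVs, label table, gene/symbol lists and ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for omic in OMICS:
            p = out / f"{omic}.tsv"
            self.matrix(omic).write_tsv(p)
            paths[omic] = p
        paths["labels"] = out / "labels.tsv"
        with open(paths["labels"], "w") as fh:
            for s in self.expression.sample_ids:
                fh.write(f"{s}\t{self.class_names[self.labels[s]]}\n")
        paths["gene_list"] = out / "gene_list.txt"
        paths["gene_list"].write_text("".join(f"{g}\n" for g in self.gene_list))
        paths["approved_symbols"] = out / "approved_symbols.txt"
        paths["approved_symbols"].write_text(
            "".join(f"{g}\n" for g in self.approved_symbols)
        )
        paths["ground_truth"] = out / "ground_truth.json"
        paths["ground_truth"].write_text(json.dumps(self.ground_truth, indent=1))
        return paths


def _class_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n samples to the class simplex."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _default_class_names(k: int) -> list[str]:
    if k == 3:
        # Gleason groups: 3+4, 4+3, and >=8 pooled.
        return ["gleason_3p4", "gleason_4p3", "gleason_ge8"]
    return [f"class_{i}" for i in range(k)]


def generate_multiomics(spec: SyntheticSpec) -> GeneratedData:
    """Draw one dataset under ``spec``; byte-reproducible from the seed.

    For class ``c`` and signal gene ``g``, omic values are Gaussian around
    ``base(g, omic) + c * effect_size`` (sd ``noise_sd``), truncated to
    [0, 1].  Non-signal genes are class-independent noise; a
    ``frac_low_variance`` slice is near-constant (sd ``low_variance_sd``)
    and a ``frac_bad_symbols`` slice carries probe-style names absent from
    the approved list.  The methylation table omits a
    ``missing_sample_frac`` slice of samples.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_classes

    counts = _class_counts(n, np.asarray(spec.class_proportions))
    y = rng.permutation(np.repeat(np.arange(k), counts))
    sample_ids = [f"SAMP{i:04d}" for i in range(n)]
    class_names = _default_class_names(k)
    labels = {s: int(c) for s, c in zip(sample_ids, y)}

    # Gene roles: signal, low-variance filler, bad-symbol filler, plain filler.
    n_low = round(spec.frac_low_variance * spec.n_genes_raw)
    n_bad = round(spec.frac_bad_symbols * spec.n_genes_raw)
    signal = list(_SIGNAL_SYMBOLS[: spec.n_genes_signal])
    signal += [f"SIG{i:03d}" for i in range(len(signal), spec.n_genes_signal)]
    bad = [f"{rng.integers(1000, 99999)}_at" for _ in range(n_bad)]
    bad = [f"{b}.{i}" for i, b in enumerate(bad)]  # force uniqueness
    n_plain = spec.n_genes_raw - spec.n_genes_signal - n_low - n_bad
    plain = [f"GENE{i:04d}" for i in range(n_plain)]
    lowvar = [f"LOWV{i:04d}" for i in range(n_low)]

    gene_ids = signal + plain + lowvar + bad
    order = rng.permutation(len(gene_ids))
    gene_ids = [gene_ids[i] for i in order]
    role = {}
    for g in signal:
        role[g] = "signal"
    for g in plain:
        role[g] = "plain"
    for g in lowvar:
        role[g] = "low_variance"
    for g in bad:
        role[g] = "bad_symbol"

    # Methylation drops a slice of samples (complete-case intersection).
    n_drop = round(spec.missing_sample_frac * n)
    dropped = set(rng.choice(n, size=n_drop, replace=False).tolist())
    meth_cols = [j for j in range(n) if j not in dropped]

    true_means: dict[str, dict[str, list[float]]] = {}
    matrices = {}
    for omic in OMICS:
        vals = np.empty((len(gene_ids), n))
        for gi, g in enumerate(gene_ids):
            if role[g] == "signal":
                base = rng.uniform(0.25, 0.45)
                mean = base + y * spec.effect_size
                sd = spec.noise_sd
                true_means.setdefault(g, {})[omic] = [
                    float(base + c * spec.effect_size) for c in range(k)
                ]
            elif role[g] == "low_variance":
                mean = np.full(n, rng.uniform(0.2, 0.8))
                sd = spec.low_variance_sd
            else:
                mean = np.full(n, rng.uniform(0.2, 0.8))
                sd = spec.noise_sd
            vals[gi] = np.clip(rng.normal(mean, sd), 0.0, 1.0)
        cols = meth_cols if omic == "methylation" else range(n)
        matrices[omic] = FeatureMatrix(
            omic_kind=OmicKind(omic),
            gene_ids=list(gene_ids),
            sample_ids=[sample_ids[j] for j in cols],
            values=vals[:, list(cols)],
        )

    approved = sorted(g for g in gene_ids if role[g] != "bad_symbol")
    ground_truth = {
        "spec": {
            "n_samples": n, "n_genes_raw": spec.n_genes_raw,
            "n_genes_signal": spec.n_genes_signal, "n_classes": k,
            "effect_size": spec.effect_size, "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
        "class_names": class_names,
        "class_counts": counts.tolist(),
        "signal_genes": signal,
        "low_variance_genes": sorted(lowvar),
        "bad_symbol_genes": sorted(bad),
        "dropped_methylation_samples": sorted(sample_ids[j] for j in dropped),
        "true_class_means": true_means,
    }
    return GeneratedData(
        expression=matrices["expression"],
        methylation=matrices["methylation"],
        cna=matrices["cna"],
        labels=labels,
        class_names=class_names,
        gene_list=signal,
        approved_symbols=approved,
        ground_truth=ground_truth,
    )


def ground_truth_report(dataset: MultiOmicsDataset, ground_truth: dict) -> dict:
    """Recovery summary: class counts, realized effect sizes, surviving genes.

    Realized effect size for a gene/omic is the difference between
    adjacent class means of the assembled (possibly normalized) values.
    """
    y = dataset.label_vector()
    class_counts = np.bincount(y, minlength=dataset.n_classes).tolist()
    planted = ground_truth["signal_genes"]
    surviving = [g for g in planted if g in set(dataset.gene_ids)]
    realized: dict[str, dict[str, list[float]]] = {}
    for omic in OMICS:
        m = getattr(dataset, omic)
        for g in surviving:
            gi = dataset.gene_ids.index(g)
            row = m.values[gi]
            means = [float(row[y == c].mean()) for c in range(dataset.n_classes)]
            realized.setdefault(g, {})[omic] = means
    return {
        "class_counts": class_counts,
        "n_planted": len(planted),
        "surviving_planted_genes": surviving,
        "realized_class_means": realized,
    }
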