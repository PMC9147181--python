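"""Synthetic fixtures with the statistical structure the classifier assumes.

The planted-subset generator emulates the fused fingerprint matrix:
mixed binary/continuous columns with block metadata, roughly balanced
binary labels and an informative subset whose columns carry a
class-conditional signal (Bernoulli rate shift for binary columns, mean
shift at unit variance for continuous ones). Effects are independent
across features — real fingerprint bits are correlated, so passing
recovery tests here shows the machinery works, not that real data is
this easy. The multi-source label generator builds curation tables whose
per-compound agreement is controlled exactly, so each resolution branch
is exercised at known counts; its "SMILES" fields are opaque synthetic
identifiers, not parseable molecules.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .featurize import FeatureBlockSpec, FusedFeatureMatrix, SourceLabelTable


@dataclass
class SyntheticSpec:
    """Default values define the standard desk-scale fixture."""

    n_samples: int = 300
    n_binary: int = 80
    n_continuous: int = 40
    n_informative: int = 30        # |I|, split across both kinds
    p1: float = 0.8                # P(bit = 1 | y = 1) for informative binary cols
    p0: float = 0.2                # P(bit = 1 | y = 0)
    delta: float = 1.5             # class mean shift of informative continuous cols
    class_balance: float = 0.5     # rho = P(y = 1)
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.n_binary + self.n_continuous

    def validate(self) -> None:
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1
                and 0 <= self.class_balance <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_informative > self.n_features:
            raise ValueError("more informative features than features")


def generate_planted_dataset(
    spec: SyntheticSpec | None = None,
) -> tuple[FusedFeatureMatrix, np.ndarray, np.ndarray]:
    """Generate (matrix, labels, informative_indices) from a SyntheticSpec.

    Binary block occupies columns [0, n_binary); continuous block
    follows. Informative indices are drawn without replacement across
    the whole column range.
    """
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, sf = spec.n_samples, spec.n_features
    y = (rng.random(n) < spec.class_balance).astype(int)
    informative = np.sort(rng.choice(sf, size=spec.n_informative, replace=False))
    info = np.zeros(sf, dtype=bool)
    info[informative] = True

    X = np.empty((n, sf))
    for j in range(spec.n_binary):
        p = np.where(y == 1, spec.p1, spec.p0) if info[j] else 0.5
        X[:, j] = (rng.random(n) < p).astype(float)
    for j in range(spec.n_binary, sf):
        mean = spec.delta * y if info[j] else 0.0
        X[:, j] = rng.normal(mean, 1.0, size=n)

    blocks = [FeatureBlockSpec("SYNBIN", "binary", spec.n_binary, 0),
              FeatureBlockSpec("SYNCONT", "continuous", spec.n_continuous,
                               spec.n_binary)]
    kinds = np.asarray(["binary"] * spec.n_binary
                       + ["continuous"] * spec.n_continuous, dtype=object)
    matrix = FusedFeatureMatrix(X, kinds, blocks, labels=y)
    return matrix, y, informative


def generate_multisource_labels(
    n_compounds: int,
    n_sources: int,
    agreement: float,
    seed: int = 0,
    priority_sources: list[str] | None = None,
    n_priority_compounds: int = 0,
) -> SourceLabelTable:
    """Build a curation table with an exact per-compound agreement fraction.

    Every compound gets one row per source; exactly
    ``round(agreement * n_sources)`` sources carry the compound's true
    label, the rest the flipped label (assignment randomized per
    compound). The first ``n_priority_compounds`` compounds additionally
    get a row in the top priority source carrying the *flipped* label,
    so priority override is observable against the consensus.
    """
    if n_sources < 2:
        raise ValueError("need at least two sources")
    rng = np.random.default_rng(seed)
    sources = [f"source_{i}" for i in range(n_sources)]
    n_agree = int(round(agreement * n_sources))
    rows = []
    for i in range(n_compounds):
        smiles = f"SYN-{i:05d}"
        true = int(rng.integers(2))
        carriers = rng.permutation(n_sources)
        for pos, src_idx in enumerate(carriers):
            label = true if pos < n_agree else 1 - true
            rows.append((smiles, sources[src_idx], label))
        if priority_sources and i < n_priority_compounds:
            rows.append((smiles, priority_sources[0], 1 - true))
    table = pd.DataFrame(rows, columns=["canonical_smiles", "source_id", "label"])
    return SourceLabelTable(table, priority_sources=priority_sources or [])
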