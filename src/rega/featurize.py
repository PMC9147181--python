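"""SMILES curation, fingerprint fusion and min-max normalization.

The featurizer turns SMILES strings into a single fused matrix of four
fingerprint blocks laid side by side:

=========  ==========  =====
block      kind        width
=========  ==========  =====
ECFP2      binary      2048  (circular fingerprint, radius 1, hashed)
MACCS      binary       167  (structural key dictionary)
RDKIT2D    continuous   200  (pinned 2D physicochemical descriptor set)
PUBCHEM    binary       881  (CACTVS-layout substructure keys)
=========  ==========  =====

Curation resolves conflicting hepatotoxicity labels collected from
several literature sources: a configurable ordered list of priority
sources overrides everything else, and the remaining compounds are kept
only when at least 80% of their sources agree on the label.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.preprocessing import MinMaxScaler

from .pubchem import N_BITS as PUBCHEM_BITS, pubchem_fingerprint

logger = logging.getLogger(__name__)

BLOCK_ORDER = ("ECFP2", "MACCS", "RDKIT2D", "PUBCHEM")
BLOCK_WIDTHS = {"ECFP2": 2048, "MACCS": 167, "RDKIT2D": 200, "PUBCHEM": PUBCHEM_BITS}
BLOCK_KINDS = {"ECFP2": "binary", "MACCS": "binary",
               "RDKIT2D": "continuous", "PUBCHEM": "binary"}

#: Elements allowed by default during curation; molecules containing any
#: other element (all metals, noble gases, rare elements) are removed.
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MoleculeRecord:
    raw_smiles: str
    canonical_smiles: str | None = None
    label: int | None = None
    source_id: str = ""


@dataclass
class SourceLabelTable:
    """Rows of (canonical_smiles, source_id, label) plus a priority order."""

    rows: pd.DataFrame
    priority_sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"canonical_smiles", "source_id", "label"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"label table missing columns: {sorted(missing)}")


@dataclass(frozen=True)
class FeatureBlockSpec:
    name: str
    kind: str            # binary | continuous
    width: int
    offset: int

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous", "mixed"):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.width <= 0:
            raise ValueError("block width must be positive")


@dataclass
class FusedFeatureMatrix:
    """Samples x features with per-column kind and block provenance."""

    values: np.ndarray
    column_kinds: np.ndarray          # length-Sf array of "binary"/"continuous"
    blocks: list[FeatureBlockSpec]
    labels: np.ndarray | None = None
    normalization: dict | None = None  # {"min": array, "max": array} once normalized

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        self.column_kinds = np.asarray(self.column_kinds, dtype=object)
        if len(self.column_kinds) != self.values.shape[1]:
            raise ValueError("column_kinds length does not match column count")
        total = sum(b.width for b in self.blocks)
        if total != self.values.shape[1]:
            raise ValueError(f"blocks tile {total} columns but matrix has "
                             f"{self.values.shape[1]}")
        off = 0
        for b in self.blocks:
            if b.offset != off:
                raise ValueError("blocks must tile the column range without gaps")
            off += b.width
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_normalized(self) -> bool:
        return self.normalization is not None

    def column_names(self) -> list[str]:
        names = []
        for b in self.blocks:
            names.extend(f"{b.name}_{i}" for i in range(b.width))
        return names

    def block_columns(self, name: str) -> np.ndarray:
        for b in self.blocks:
            if b.name == name:
                return np.arange(b.offset, b.offset + b.width)
        raise KeyError(f"unknown block {name!r}; have "
                       f"{[b.name for b in self.blocks]}")

    def select_blocks(self, names: Sequence[str]) -> "FusedFeatureMatrix":
        """Restrict the matrix to the named blocks (original block order kept)."""
        keep = [b for b in self.blocks if b.name in set(names)]
        unknown = set(names) - {b.name for b in self.blocks}
        if unknown:
            raise KeyError(f"unknown block(s) {sorted(unknown)}")
        cols, new_blocks, off = [], [], 0
        for b in keep:
            cols.extend(range(b.offset, b.offset + b.width))
            new_blocks.append(replace(b, offset=off))
            off += b.width
        cols = np.asarray(cols, dtype=int)
        norm = None
        if self.normalization is not None:
            norm = {"min": self.normalization["min"][cols],
                    "max": self.normalization["max"][cols]}
        return FusedFeatureMatrix(self.values[:, cols], self.column_kinds[cols],
                                  new_blocks, labels=self.labels,
                                  normalization=norm)

    # -- persistence --------------------------------------------------------
    def to_csv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        path = Path(path)
        df = pd.DataFrame(self.values, columns=self.column_names())
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, index=False, float_format="%.17g")  # exact roundtrip
        meta = {
            "blocks": [{"name": b.name, "kind": b.kind, "width": b.width,
                        "offset": b.offset} for b in self.blocks],
            "column_kinds": list(self.column_kinds),
            "normalization": None if self.normalization is None else {
                "min": list(map(float, self.normalization["min"])),
                "max": list(map(float, self.normalization["max"])),
            },
        }
        meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
        meta_path.write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path,
                 metadata_path: str | Path | None = None) -> "FusedFeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy()
        meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text())
        blocks = [FeatureBlockSpec(**b) for b in meta["blocks"]]
        norm = meta.get("normalization")
        if norm is not None:
            norm = {"min": np.asarray(norm["min"]), "max": np.asarray(norm["max"])}
        return cls(df.to_numpy(dtype=float), np.asarray(meta["column_kinds"]),
                   blocks, labels=labels, normalization=norm)


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def canonicalize_smiles(smiles: str) -> str | None:
    """Canonical SMILES via RDKit, or None when unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def canonicalize_and_dedupe(
    records: Iterable[MoleculeRecord],
    allowed_elements: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS,
) -> list[MoleculeRecord]:
    """Canonicalize, drop unparseable/metal-containing molecules, dedupe per source.

    Within each source the first record per canonical SMILES is kept.
    Molecules containing any element outside ``allowed_elements`` (by
    default: any metal or rare element) are removed.
    """
    out: list[MoleculeRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if not rec.raw_smiles:
            raise ValueError("raw_smiles must be nonempty")
        mol = Chem.MolFromSmiles(rec.raw_smiles)
        if mol is None:
            logger.warning("dropping unparseable SMILES %r (source %s)",
                           rec.raw_smiles, rec.source_id)
            continue
        symbols = {a.GetSymbol() for a in mol.GetAtoms()}
        if not symbols <= allowed_elements:
            logger.info("dropping %r: disallowed element(s) %s",
                        rec.raw_smiles, sorted(symbols - allowed_elements))
            continue
        canonical = Chem.MolToSmiles(mol)
        key = (rec.source_id, canonical)
        if key in seen:
            continue
        seen.add(key)
        out.append(replace(rec, canonical_smiles=canonical))
    return out


def resolve_labels(table: SourceLabelTable,
                   consensus: float = 0.8) -> pd.DataFrame:
    """Resolve multi-source labels into one row per surviving compound.

    A compound found in any priority source takes the label of the
    highest-priority source that lists it, ignoring all other sources.
    Otherwise the majority label is kept iff its agreement fraction is at
    least ``consensus`` (default 80%); compounds below the threshold are
    dropped, as are compounds whose winning priority source is internally
    inconsistent.
    """
    rows = table.rows.drop_duplicates(subset=["canonical_smiles", "source_id"])
    if rows.empty:
        raise ValueError("label table is empty")
    bad = set(rows["label"].unique()) - {0, 1}
    if bad:
        raise ValueError(f"labels must be 0/1; found {sorted(bad)}")
    rank = {s: i for i, s in enumerate(table.priority_sources)}
    resolved = []
    for smiles, grp in rows.groupby("canonical_smiles", sort=True):
        prio = grp[grp["source_id"].isin(rank)]
        if not prio.empty:
            best = min(rank[s] for s in prio["source_id"])
            top = prio[prio["source_id"].map(rank) == best]
            labels = top["label"].unique()
            if len(labels) > 1:
                logger.warning("dropping %s: top-priority sources disagree", smiles)
                continue
            resolved.append((smiles, int(labels[0])))
            continue
        counts = grp["label"].value_counts()
        majority = counts.idxmax()
        agreement = counts.max() / counts.sum()
        if agreement >= consensus:
            resolved.append((smiles, int(majority)))
        else:
            logger.info("dropping %s: agreement %.2f < %.2f",
                        smiles, agreement, consensus)
    return pd.DataFrame(resolved, columns=["canonical_smiles", "label"])


# ---------------------------------------------------------------------------
# fingerprint fusion
# ---------------------------------------------------------------------------

def _rdkit2d_names() -> list[str]:
    text = resources.files("rega.data").joinpath("rdkit2d_descriptors.txt").read_text()
    names = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    if len(names) != BLOCK_WIDTHS["RDKIT2D"]:
        raise RuntimeError("pinned descriptor list is corrupt")
    return names


def _rdkit2d_row(mol: Chem.Mol, names: list[str],
                 fns: dict[str, object], smiles: str) -> np.ndarray:
    vals = np.empty(len(names))
    for i, name in enumerate(names):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                v = float(fns[name](mol))
            except Exception:  # descriptor failure -> treated like NaN
                v = np.nan
        if not np.isfinite(v):
            logger.warning("descriptor %s is not finite for %r; using 0", name, smiles)
            v = 0.0
        vals[i] = v
    return vals


def compute_fused_fingerprints(
    smiles: Sequence[str],
    enabled_blocks: Sequence[str] = BLOCK_ORDER,
) -> FusedFeatureMatrix:
    """Featurize SMILES into the fused fingerprint matrix.

    Blocks appear in the fixed order ECFP2, MACCS, RDKIT2D, PUBCHEM
    restricted to ``enabled_blocks``. Unparseable SMILES raise a
    ``ValueError`` naming the offending row; non-finite descriptor values
    are replaced by 0 with a warning.
    """
    enabled = [b for b in BLOCK_ORDER if b.upper() in {e.upper() for e in enabled_blocks}]
    unknown = {e.upper() for e in enabled_blocks} - set(BLOCK_ORDER)
    if unknown:
        raise KeyError(f"unknown block(s) {sorted(unknown)}; valid: {BLOCK_ORDER}")
    if not enabled:
        raise ValueError("enabled_blocks must be nonempty")

    mols = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES at row {i}: {smi!r}")
        mols.append(mol)

    morgan = rdFingerprintGenerator.GetMorganGenerator(radius=1, fpSize=2048)
    desc_names = _rdkit2d_names() if "RDKIT2D" in enabled else []
    desc_fns = dict(Descriptors._descList)

    parts: dict[str, np.ndarray] = {}
    n = len(mols)
    for name in enabled:
        width = BLOCK_WIDTHS[name]
        arr = np.zeros((n, width))
        for i, mol in enumerate(mols):
            if name == "ECFP2":
                arr[i] = np.frombuffer(
                    bytes(morgan.GetFingerprint(mol).ToBitString(), "ascii"),
                    dtype=np.uint8) - ord("0")
            elif name == "MACCS":
                fp = MACCSkeys.GenMACCSKeys(mol)
                arr[i] = np.frombuffer(bytes(fp.ToBitString(), "ascii"),
                                       dtype=np.uint8) - ord("0")
            elif name == "RDKIT2D":
                arr[i] = _rdkit2d_row(mol, desc_names, desc_fns, smiles[i])
            else:
                arr[i] = pubchem_fingerprint(mol)
        parts[name] = arr

    blocks, off = [], 0
    kinds: list[str] = []
    for name in enabled:
        width = BLOCK_WIDTHS[name]
        blocks.append(FeatureBlockSpec(name, BLOCK_KINDS[name], width, off))
        kinds.extend([BLOCK_KINDS[name]] * width)
        off += width
    values = np.hstack([parts[name] for name in enabled])
    return FusedFeatureMatrix(values, np.asarray(kinds, dtype=object), blocks)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class MinMaxNormalizer:
    """Per-column min-max scaling x' = (x - min x)/(max x - min x).

    Fit on training rows only; transformed values are clipped to [0, 1]
    so held-out rows cannot leave the unit interval. Constant columns map
    to 0. Thin wrapper over :class:`sklearn.preprocessing.MinMaxScaler`.
    """

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("cannot fit normalizer on zero rows")
        self._scaler = MinMaxScaler(clip=True).fit(X)
        self.data_min_ = self._scaler.data_min_
        self.data_max_ = self._scaler.data_max_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._scaler.transform(np.asarray(X, dtype=float))

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def minmax_fit_apply(matrix: FusedFeatureMatrix,
                     fit_rows: Sequence[int] | None = None) -> FusedFeatureMatrix:
    """Return a normalized copy of ``matrix``; min/max come from ``fit_rows`` only."""
    if matrix.is_normalized:
        raise ValueError("matrix is already normalized")
    rows = np.arange(matrix.n_samples) if fit_rows is None else np.asarray(fit_rows)
    if rows.size == 0:
        raise ValueError("fit_rows must be nonempty")
    norm = MinMaxNormalizer().fit(matrix.values[rows])
    return FusedFeatureMatrix(
        norm.transform(matrix.values), matrix.column_kinds, list(matrix.blocks),
        labels=matrix.labels,
        normalization={"min": norm.data_min_.copy(), "max": norm.data_max_.copy()},
    )


# ---------------------------------------------------------------------------
# generic external tables
# ---------------------------------------------------------------------------

def load_feature_table(path: str | Path, kinds: Sequence[str],
                       block_name: str = "USER") -> FusedFeatureMatrix:
    """Load an externally computed descriptor table as a single-block matrix.

    ``kinds`` declares each column binary or continuous; declared-binary
    columns are validated to contain only {0, 1}.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"empty feature table: {path}")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy()
    if len(kinds) != df.shape[1]:
        raise ValueError(f"kinds has {len(kinds)} entries for {df.shape[1]} columns")
    values = df.to_numpy(dtype=float)
    for j, kind in enumerate(kinds):
        if kind == "binary":
            col = values[:, j]
            if not np.isin(col, (0.0, 1.0)).all():
                raise ValueError(
                    f"column {df.columns[j]!r} declared binary but contains "
                    f"non-binary values")
        elif kind != "continuous":
            raise ValueError(f"unknown column kind {kind!r}")
    block_kind = ("binary" if all(k == "binary" for k in kinds)
                  else "continuous" if all(k == "continuous" for k in kinds)
                  else "mixed")
    blocks = [FeatureBlockSpec(block_name, block_kind, df.shape[1], 0)]
    return FusedFeatureMatrix(values, np.asarray(kinds, dtype=object), blocks,
                              labels=labels)
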