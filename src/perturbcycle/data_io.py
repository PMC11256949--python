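"""Expression dataset I/O, perturbation-level splitting, and pair assembly.

Supported on-disk forms:

* H5AD — AnnData layout: ``X`` matrix, ``obs`` carrying the perturbation
  metadata columns, ``var`` index carrying gene identifiers.
* MatrixMarket — ``.mtx`` (samples x genes) with sidecar ``*_features.txt``
  (gene ids, one per line), ``*_barcodes.txt`` (sample ids) and an
  ``*_obs.csv`` metadata table.
* Delimited text — comma-separated (tab autodetected), header row of gene
  ids, first column ``sample_id``; metadata joined from a sidecar
  ``*_obs.csv`` or embedded reserved columns.

Expression values are consumed as provided; an optional ``log1p`` +
per-gene standardization preprocessing flag exists but defaults off.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PerturbationKind",
    "PerturbationRecord",
    "ExpressionDataset",
    "SplitSpec",
    "DataError",
    "load_expression",
    "write_expression",
    "split_by_perturbation",
    "build_pairs",
    "preprocess",
]

CONTROL_ID = "control"

#: obs columns recognized when loading metadata
_META_COLUMNS = ("perturbation_id", "kind", "smiles", "target_gene", "dose", "context_id")


class DataError(ValueError):
    """Structured error for malformed input tables."""


class PerturbationKind(str, enum.Enum):
    DRUG = "drug"
    GENETIC = "genetic"
    CONTROL = "control"


@dataclasses.dataclass(frozen=True)
class PerturbationRecord:
    """Metadata for one sample: what was done to it and in which context."""

    sample_id: str
    perturbation_id: str
    kind: PerturbationKind
    smiles: Optional[str] = None
    target_gene: Optional[str] = None
    dose: Optional[float] = None
    context_id: str = "global"

    def __post_init__(self):
        if self.kind == PerturbationKind.DRUG and not self.smiles:
            raise DataError(f"sample {self.sample_id}: drug perturbation requires a SMILES")
        if self.kind == PerturbationKind.GENETIC and not self.target_gene:
            raise DataError(f"sample {self.sample_id}: genetic perturbation requires a target gene")
        if self.kind == PerturbationKind.CONTROL and (self.smiles or self.target_gene):
            raise DataError(f"sample {self.sample_id}: control must carry no SMILES/target")
        if self.dose is not None and (not math.isfinite(self.dose) or self.dose < 0):
            raise DataError(f"sample {self.sample_id}: dose must be finite and nonnegative")

    @property
    def is_control(self) -> bool:
        return self.kind == PerturbationKind.CONTROL


class ExpressionDataset:
    """A samples x genes matrix with aligned per-sample perturbation records.

    ``pairing`` optionally maps treated row index -> control row index.
    ``graphs`` optionally maps perturbation_id -> DrugGraph for perturbations
    whose structure is supplied directly rather than via SMILES.
    """

    def __init__(
        self,
        matrix: np.ndarray,
        records: Sequence[PerturbationRecord],
        gene_ids: Sequence[str],
        pairing: Optional[dict[int, int]] = None,
        graphs: Optional[dict] = None,
    ):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            raise DataError("expression matrix must be 2-D (samples x genes)")
        if matrix.shape[0] != len(records):
            raise DataError(
                f"matrix has {matrix.shape[0]} rows but {len(records)} records"
            )
        if matrix.shape[1] != len(gene_ids):
            raise DataError(
                f"matrix has {matrix.shape[1]} columns but {len(gene_ids)} gene ids"
            )
        if not np.all(np.isfinite(matrix)):
            bad = np.argwhere(~np.isfinite(matrix))[0]
            raise DataError(f"non-finite expression value at row {bad[0]}, column {bad[1]}")
        if pairing is not None:
            ctrl_rows = {i for i, r in enumerate(records) if r.is_control}
            targets = list(pairing.values())
            if not set(targets) <= ctrl_rows:
                raise DataError("pairing maps to non-control rows")
        self.matrix = matrix
        self.records = list(records)
        self.gene_ids = [str(g) for g in gene_ids]
        self.pairing = dict(pairing) if pairing is not None else None
        self.graphs = dict(graphs) if graphs is not None else None

    # -- basic views ----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def control_rows(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.records) if r.is_control], dtype=int)

    def treated_rows(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.records) if not r.is_control], dtype=int)

    def perturbation_ids(self, include_control: bool = False) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if r.is_control and not include_control:
                continue
            seen.setdefault(r.perturbation_id, None)
        return list(seen)

    def subset(self, rows: Sequence[int]) -> "ExpressionDataset":
        rows = list(rows)
        old_to_new = {old: new for new, old in enumerate(rows)}
        pairing = None
        if self.pairing is not None:
            pairing = {
                old_to_new[t]: old_to_new[c]
                for t, c in self.pairing.items()
                if t in old_to_new and c in old_to_new
            }
        return ExpressionDataset(
            self.matrix[rows],
            [self.records[i] for i in rows],
            self.gene_ids,
            pairing=pairing,
            graphs=self.graphs,
        )

    def obs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "perturbation_id": [r.perturbation_id for r in self.records],
                "kind": [r.kind.value for r in self.records],
                "smiles": [r.smiles if r.smiles is not None else "" for r in self.records],
                "target_gene": [
                    r.target_gene if r.target_gene is not None else "" for r in self.records
                ],
                "dose": [r.dose if r.dose is not None else np.nan for r in self.records],
                "context_id": [r.context_id for r in self.records],
            }
        )


def _records_from_frame(obs: pd.DataFrame) -> list[PerturbationRecord]:
    for col in ("perturbation_id", "kind"):
        if col not in obs.columns:
            raise DataError(f"metadata table is missing required column '{col}'")
    records = []
    for _, row in obs.iterrows():
        kind_raw = str(row["kind"]).strip().lower()
        try:
            kind = PerturbationKind(kind_raw)
        except ValueError:
            raise DataError(
                f"sample {row.get('sample_id', '?')}: unknown perturbation kind '{kind_raw}'"
            ) from None
        smiles = row.get("smiles")
        smiles = None if (smiles is None or (isinstance(smiles, float) and math.isnan(smiles)) or str(smiles) == "") else str(smiles)
        target = row.get("target_gene")
        target = None if (target is None or (isinstance(target, float) and math.isnan(target)) or str(target) == "") else str(target)
        dose = row.get("dose")
        dose = None if (dose is None or (isinstance(dose, float) and math.isnan(dose)) or str(dose) == "") else float(dose)
        records.append(
            PerturbationRecord(
                sample_id=str(row.get("sample_id", f"S{len(records)}")),
                perturbation_id=str(row["perturbation_id"]),
                kind=kind,
                smiles=smiles,
                target_gene=target,
                dose=dose,
                context_id=str(row.get("context_id", "global")),
            )
        )
    return records


# ---------------------------------------------------------------------------
# load / write
# ---------------------------------------------------------------------------


def load_expression(path, format: str) -> ExpressionDataset:
    """Read an expression dataset with aligned perturbation metadata."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format == "h5ad":
        return _load_h5ad(path)
    if format == "mtx":
        return _load_mtx(path)
    if format == "delimited":
        return _load_delimited(path)
    raise DataError(f"unknown format '{format}' (expected h5ad, mtx or delimited)")


def write_expression(ds: ExpressionDataset, path, format: str) -> None:
    path = Path(path)
    if format == "h5ad":
        _write_h5ad(ds, path)
    elif format == "mtx":
        _write_mtx(ds, path)
    elif format == "delimited":
        _write_delimited(ds, path)
    else:
        raise DataError(f"unknown format '{format}' (expected h5ad, mtx or delimited)")


def _load_h5ad(path: Path) -> ExpressionDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.X
    if not isinstance(X, np.ndarray):
        X = X.toarray()
    obs = adata.obs.reset_index().rename(columns={"index": "sample_id"})
    if "sample_id" not in obs.columns:
        obs["sample_id"] = adata.obs_names
    return ExpressionDataset(np.asarray(X, dtype=np.float64), _records_from_frame(obs), list(adata.var_names))


def _write_h5ad(ds: ExpressionDataset, path: Path) -> None:
    import anndata as ad

    obs = ds.obs_frame()
    obs.index = obs["sample_id"].astype(str)
    obs = obs.drop(columns=["sample_id"])
    obs.index.name = None
    adata = ad.AnnData(X=ds.matrix.copy(), obs=obs, var=pd.DataFrame(index=ds.gene_ids))
    adata.write_h5ad(path)


def _sidecar(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix)


def _load_mtx(path: Path) -> ExpressionDataset:
    from scipy.io import mmread

    raw = mmread(path)
    matrix = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
    features = _sidecar(path, "_features.txt")
    obs_path = _sidecar(path, "_obs.csv")
    if not features.exists():
        raise DataError(f"missing sidecar features file: {features}")
    if not obs_path.exists():
        raise DataError(f"missing sidecar metadata file: {obs_path}")
    gene_ids = features.read_text().split()
    obs = pd.read_csv(obs_path)
    return ExpressionDataset(matrix.astype(np.float64), _records_from_frame(obs), gene_ids)


def _write_mtx(ds: ExpressionDataset, path: Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(str(path), coo_matrix(ds.matrix))
    # mmwrite appends .mtx if absent; normalize
    written = path if path.exists() else path.with_suffix(path.suffix + ".mtx")
    if written != path and written.exists():
        written.rename(path)
    _sidecar(path, "_features.txt").write_text("\n".join(ds.gene_ids) + "\n")
    _sidecar(path, "_barcodes.txt").write_text(
        "\n".join(r.sample_id for r in ds.records) + "\n"
    )
    ds.obs_frame().to_csv(_sidecar(path, "_obs.csv"), index=False)


def _detect_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") > head.count(",") else ","


def _load_delimited(path: Path) -> ExpressionDataset:
    sep = _detect_sep(path)
    frame = pd.read_csv(path, sep=sep)
    if frame.columns[0] != "sample_id":
        raise DataError("delimited file must have 'sample_id' as its first column")
    meta_cols = [c for c in frame.columns if c in _META_COLUMNS]
    gene_cols = [c for c in frame.columns[1:] if c not in _META_COLUMNS]
    values = frame[gene_cols]
    non_numeric = values.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
    if non_numeric.any().any():
        r, c = np.argwhere(non_numeric.values)[0]
        raise DataError(
            f"non-numeric expression value at row {r}, column '{gene_cols[c]}'"
        )
    obs_path = _sidecar(path, "_obs.csv")
    if meta_cols:
        obs = frame[["sample_id"] + meta_cols]
    elif obs_path.exists():
        obs = pd.read_csv(obs_path)
    else:
        raise DataError(
            "no perturbation metadata: expected embedded columns "
            f"{_META_COLUMNS[:2]} or sidecar {obs_path.name}"
        )
    return ExpressionDataset(
        values.to_numpy(dtype=np.float64), _records_from_frame(obs), gene_cols
    )


def _write_delimited(ds: ExpressionDataset, path: Path) -> None:
    frame = pd.DataFrame(ds.matrix, columns=ds.gene_ids)
    frame.insert(0, "sample_id", [r.sample_id for r in ds.records])
    frame.to_csv(path, index=False)
    ds.obs_frame().to_csv(_sidecar(path, "_obs.csv"), index=False)


# ---------------------------------------------------------------------------
# splitting and pairing
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    level: str = "perturbation"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if self.level not in ("sample", "perturbation"):
            raise DataError(f"unknown split level '{self.level}'")
        if any(f < 0 or f > 1 for f in self.fractions):
            raise DataError("split fractions must lie in [0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise DataError(f"split fractions must sum to 1, got {sum(self.fractions)}")


def _assign_perturbations(
    pert_ids: Sequence[str], fractions: tuple[float, float, float], seed: int
) -> tuple[list[str], list[str], list[str]]:
    """Shuffle the sorted perturbation list with a seeded generator and slice."""
    rng = np.random.default_rng(seed)
    ids = sorted(pert_ids)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def split_by_perturbation(
    ds: ExpressionDataset, spec: SplitSpec
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Partition all non-control perturbations into train/val/test.

    Every data point of a given perturbation lands in exactly one split;
    control samples are replicated into each split (controls are inputs,
    not prediction targets).
    """
    if spec.level != "perturbation":
        raise DataError("split_by_perturbation requires spec.level='perturbation'")
    pert_ids = ds.perturbation_ids()
    if len(pert_ids) < 3:
        raise DataError(f"need >=3 distinct non-control perturbations, got {len(pert_ids)}")
    n_nonzero = sum(1 for f in spec.fractions if f > 0)
    if len(pert_ids) < n_nonzero:
        raise DataError(
            f"{len(pert_ids)} perturbations cannot populate {n_nonzero} nonzero splits"
        )
    groups = _assign_perturbations(pert_ids, spec.fractions, spec.seed)
    ctrl = list(ds.control_rows())
    out = []
    for members in groups:
        members = set(members)
        rows = ctrl + [
            i
            for i, r in enumerate(ds.records)
            if not r.is_control and r.perturbation_id in members
        ]
        out.append(ds.subset(rows))
    return tuple(out)


@dataclasses.dataclass
class PairedSet:
    """Aligned (control, treated, record) triples for paired training."""

    x: np.ndarray  # controls, n x G
    y: np.ndarray  # treated, n x G
    records: list[PerturbationRecord]  # treated-row records, length n
    gene_ids: list[str]
    graphs: Optional[dict] = None

    def __len__(self) -> int:
        return self.x.shape[0]


@dataclasses.dataclass
class UnpairedSet:
    """Two unaligned pools: controls and labeled treated samples."""

    controls: np.ndarray
    treated: np.ndarray
    treated_records: list[PerturbationRecord]
    gene_ids: list[str]
    graphs: Optional[dict] = None


def build_pairs(ds: ExpressionDataset, mode: str):
    """Assemble a training-ready dataset in ``paired`` or ``unpaired`` mode.

    Paired mode resolves each treated row to its control through the explicit
    pairing map or, failing that, a context_id join against a unique control
    row per context.
    """
    if mode not in ("paired", "unpaired"):
        raise DataError(f"unknown pairing mode '{mode}'")
    treated = ds.treated_rows()
    controls = ds.control_rows()
    if mode == "unpaired":
        return UnpairedSet(
            controls=ds.matrix[controls],
            treated=ds.matrix[treated],
            treated_records=[ds.records[i] for i in treated],
            gene_ids=ds.gene_ids,
            graphs=ds.graphs,
        )

    pair_of: dict[int, int] = {}
    if ds.pairing is not None:
        pair_of = dict(ds.pairing)
        orphans = [ds.records[i].sample_id for i in treated if i not in pair_of]
        if orphans:
            raise DataError(f"paired mode: treated samples without a control: {orphans}")
    else:
        by_context: dict[str, list[int]] = {}
        for i in controls:
            by_context.setdefault(ds.records[i].context_id, []).append(i)
        missing = sorted(
            {
                ds.records[i].context_id
                for i in treated
                if ds.records[i].context_id not in by_context
            }
        )
        if missing:
            raise DataError(f"paired mode: contexts without a control sample: {missing}")
        counters: dict[str, int] = {}
        for i in treated:
            ctx = ds.records[i].context_id
            pool = by_context[ctx]
            k = counters.get(ctx, 0)
            pair_of[i] = pool[k % len(pool)]
            counters[ctx] = k + 1

    rows = list(treated)
    return PairedSet(
        x=ds.matrix[[pair_of[i] for i in rows]],
        y=ds.matrix[rows],
        records=[ds.records[i] for i in rows],
        gene_ids=ds.gene_ids,
        graphs=ds.graphs,
    )


def preprocess(ds: ExpressionDataset, log1p: bool = False, standardize: bool = False) -> ExpressionDataset:
    """Optional log1p + per-gene standardization; off by default."""
    matrix = ds.matrix
    if log1p:
        if (matrix < 0).any():
            raise DataError("log1p preprocessing requires nonnegative values")
        matrix = np.log1p(matrix)
    if standardize:
        mu = matrix.mean(axis=0, keepdims=True)
        sd = matrix.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        matrix = (matrix - mu) / sd
    return ExpressionDataset(matrix, ds.records, ds.gene_ids, pairing=ds.pairing, graphs=ds.graphs)
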