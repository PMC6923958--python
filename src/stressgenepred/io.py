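"""Reading and writing the package's tab-separated interchange formats.

All tables are UTF-8 TSV with a header row.  The expression table is *long*
format — ``sample_id, gene_id, time, replicate, value`` — because samples
carry heterogeneous time grids that a wide matrix cannot represent
uniformly.  Expression values are stored at 6 decimal places, which is
sufficient for microarray/RNA-seq-scale intensities and makes text
round-trips bit-stable at that precision.

Vocabularies are ordered.  When not supplied, the gene vocabulary is the
order of first appearance in the expression table, and the stress
vocabulary places the canonical names (cold, heat, salt, drought) first,
followed by any additional labels in sorted order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import DEFAULT_STRESSES, PredictionParams, StressGeneLayer, TimeSeriesSample
from .discovery import RankedGene
from .exceptions import ConsistencyError, FormatError, ParseError
from .prediction import UNCLASSIFIABLE

EXPRESSION_COLUMNS = ["sample_id", "gene_id", "time", "replicate", "value"]
METADATA_COLUMNS = ["sample_id", "stress"]

#: Recognised run-configuration keys and their defaults.
CONFIG_DEFAULTS: dict = {
    "alpha": 0.06,
    "beta": 0.01,
    "fc_threshold": 0.8,
    "epochs_discovery": 2000,
    "epochs_prediction": 500,
    "learning_rate": 0.1,
    "seed": 0,
    "top_k": 500,
}


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def _stress_vocabulary_from(labels: set[str]) -> list[str]:
    vocab = [s for s in DEFAULT_STRESSES if s in labels]
    vocab += sorted(labels - set(DEFAULT_STRESSES))
    return vocab


def read_dataset(
    expression_path,
    metadata_path,
    stress_vocabulary: list[str] | None = None,
    gene_vocabulary: list[str] | None = None,
) -> tuple[list[TimeSeriesSample], list[str], list[str]]:
    """Load a long-format expression table plus its sample metadata.

    Returns ``(samples, gene_vocabulary, stress_vocabulary)``.  Every sample
    must cover the full shared gene vocabulary; every expression sample must
    appear exactly once in the metadata; every stress label must be in the
    stress vocabulary.
    """
    expr = _read_tsv(expression_path, EXPRESSION_COLUMNS)
    meta = _read_tsv(metadata_path, METADATA_COLUMNS)

    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ConsistencyError(f"duplicate metadata row for sample {dup!r}")
    stress_of = dict(zip(meta["sample_id"], meta["stress"]))

    values = pd.to_numeric(expr["value"], errors="coerce")
    if values.isna().any():
        bad = expr.loc[values.isna(), "value"].iloc[0]
        raise ParseError(f"non-numeric expression value {bad!r}")
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ParseError("expression values must be finite and non-negative")
    times = pd.to_numeric(expr["time"], errors="coerce")
    if times.isna().any():
        raise ParseError("non-numeric time point")

    if gene_vocabulary is None:
        gene_vocabulary = list(pd.unique(expr["gene_id"]))
    gene_index = {g: i for i, g in enumerate(gene_vocabulary)}
    unknown = set(expr["gene_id"]) - set(gene_index)
    if unknown:
        raise ConsistencyError(f"genes outside the vocabulary: {sorted(unknown)[:3]}")

    sample_ids = list(pd.unique(expr["sample_id"]))
    for sid in sample_ids:
        if sid not in stress_of:
            raise ConsistencyError(f"sample {sid!r} has no metadata row")

    if stress_vocabulary is None:
        stress_vocabulary = _stress_vocabulary_from(
            {stress_of[s] for s in sample_ids}
        )
    for sid in sample_ids:
        if stress_of[sid] not in stress_vocabulary:
            raise ConsistencyError(
                f"sample {sid!r}: stress {stress_of[sid]!r} not in vocabulary"
            )

    expr = expr.assign(_value=values.to_numpy(), _time=times.to_numpy())
    samples = []
    for sid, grp in expr.groupby("sample_id", sort=False):
        genes_here = set(grp["gene_id"])
        if genes_here != set(gene_index):
            raise ConsistencyError(
                f"sample {sid!r} does not cover the shared gene vocabulary "
                f"({len(genes_here)} of {len(gene_index)} genes)"
            )
        tp = np.sort(grp["_time"].unique())
        t_index = {t: j for j, t in enumerate(tp)}
        gidx = grp["gene_id"].map(gene_index).to_numpy()
        tidx = grp["_time"].map(t_index).to_numpy()
        ridx = grp.groupby(["gene_id", "_time"], sort=False).cumcount().to_numpy()
        block = np.full((len(gene_index), len(tp), int(ridx.max()) + 1), np.nan)
        block[gidx, tidx, ridx] = grp["_value"].to_numpy()
        samples.append(
            TimeSeriesSample(
                sample_id=sid,
                stress=stress_of[sid],
                values=block,
                time_points=tp,
            )
        )
    return samples, list(gene_vocabulary), list(stress_vocabulary)


def write_dataset(
    samples: list[TimeSeriesSample],
    gene_vocabulary: list[str],
    expression_path,
    metadata_path,
) -> None:
    """Write samples as long-format expression TSV plus metadata TSV."""
    frames = []
    for s in samples:
        finite = np.isfinite(s.values)
        g, t, r = np.nonzero(finite)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "gene_id": np.asarray(gene_vocabulary, dtype=object)[g],
                    "time": s.time_points[t],
                    "replicate": r + 1,
                    "value": s.values[g, t, r],
                }
            )
        )
    expr = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=EXPRESSION_COLUMNS
    )
    expr.to_csv(expression_path, sep="\t", index=False, float_format="%.6f")
    meta = pd.DataFrame(
        {"sample_id": [s.sample_id for s in samples],
         "stress": [s.stress for s in samples]}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def write_rankings(
    rankings: dict[str, list[RankedGene]],
    path,
    stress_vocabulary: list[str] | None = None,
    gene_vocabulary: list[str] | None = None,
) -> None:
    """Write per-stress gene rankings as TSV (stress, rank, gene_id, direction, score)."""
    rows = []
    for stress, ranked in rankings.items():
        if stress_vocabulary is not None and stress not in stress_vocabulary:
            raise ConsistencyError(f"unknown stress {stress!r} in rankings")
        scores = [r.score for r in ranked]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ConsistencyError(
                f"scores for stress {stress!r} are not non-increasing"
            )
        for rank, r in enumerate(ranked, start=1):
            if gene_vocabulary is not None and r.gene not in gene_vocabulary:
                raise ConsistencyError(f"unknown gene {r.gene!r} in rankings")
            if r.direction not in ("up", "down"):
                raise ConsistencyError(f"bad direction {r.direction!r}")
            rows.append((stress, rank, r.gene, r.direction, r.score))
    df = pd.DataFrame(
        rows, columns=["stress", "rank", "gene_id", "direction", "score"]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_rankings(path) -> dict[str, list[RankedGene]]:
    df = _read_tsv(path, ["stress", "rank", "gene_id", "direction", "score"])
    out: dict[str, list[RankedGene]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["stress"], []).append(
            RankedGene(
                gene=row["gene_id"],
                direction=row["direction"],
                score=float(row["score"]),
            )
        )
    return out


def write_predictions(
    predictions: list[tuple[str, str, list[tuple[str, float]] | None]],
    path,
) -> None:
    """Write per-sample stress rankings.

    ``predictions`` holds (sample_id, true_stress, ranking) triples, the
    ranking being (stress, score) pairs sorted by score descending, or None
    for samples with no regulated genes, which are written with a single
    'unclassifiable' row.
    """
    rows = []
    for sample_id, true_stress, ranking in predictions:
        if ranking is None:
            rows.append((sample_id, true_stress, 1, UNCLASSIFIABLE, np.nan))
            continue
        for rank, (stress, score) in enumerate(ranking, start=1):
            rows.append((sample_id, true_stress, rank, stress, score))
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "true_stress", "rank", "predicted_stress", "score"],
    )
    # %g keeps tiny normalised activations meaningful (they can underflow
    # far below 1e-6 on bit-heavy samples)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_predictions(
    path,
) -> list[tuple[str, str, list[tuple[str, float]] | None]]:
    df = _read_tsv(
        path, ["sample_id", "true_stress", "rank", "predicted_stress", "score"]
    )
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("rank", key=lambda s: s.astype(int))
        true_stress = grp["true_stress"].iloc[0]
        if grp["predicted_stress"].iloc[0] == UNCLASSIFIABLE:
            out.append((sid, true_stress, None))
        else:
            out.append(
                (
                    sid,
                    true_stress,
                    [
                        (row["predicted_stress"], float(row["score"]))
                        for _, row in grp.iterrows()
                    ],
                )
            )
    return out


def feature_column_names(gene_vocabulary: list[str]) -> list[str]:
    """Interleaved <gene>_down, <gene>_up column names."""
    cols = []
    for g in gene_vocabulary:
        cols.extend([f"{g}_down", f"{g}_up"])
    return cols


def write_feature_table(
    X: np.ndarray,
    sample_ids: list[str],
    stresses: list[str],
    gene_vocabulary: list[str],
    path,
) -> None:
    """Write embedded binary features (sample_id, stress, then 2N bit columns)."""
    df = pd.DataFrame(
        np.asarray(X, dtype=int), columns=feature_column_names(gene_vocabulary)
    )
    df.insert(0, "stress", stresses)
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(
    path,
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Read a feature table; returns (X, sample_ids, stresses, gene_vocabulary)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "stress"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bit_cols = [c for c in df.columns if c not in ("sample_id", "stress")]
    genes = []
    for i in range(0, len(bit_cols), 2):
        d, u = bit_cols[i], bit_cols[i + 1] if i + 1 < len(bit_cols) else None
        if u is None or not d.endswith("_down") or not u.endswith("_up"):
            raise FormatError(f"{path}: feature columns must interleave down/up")
        if d[:-5] != u[:-3]:
            raise FormatError(f"{path}: mismatched pair {d!r}/{u!r}")
        genes.append(d[:-5])
    X = df[bit_cols].to_numpy(dtype=np.uint8)
    return X, df["sample_id"].astype(str).tolist(), df["stress"].astype(str).tolist(), genes


def write_weights(layer: StressGeneLayer, path) -> None:
    """Persist the shared layer as TSV (stress rows, gene_down/up columns)."""
    df = pd.DataFrame(
        layer.W,
        index=pd.Index(layer.stress_vocabulary, name="stress"),
        columns=feature_column_names(layer.gene_vocabulary),
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_weights(path) -> StressGeneLayer:
    df = pd.read_csv(
        path, sep="\t", index_col="stress", float_precision="round_trip"
    )
    bit_cols = list(df.columns)
    genes = [c[:-5] for c in bit_cols[0::2]]
    return StressGeneLayer(
        W=df.to_numpy(dtype=float),
        stress_vocabulary=[str(s) for s in df.index],
        gene_vocabulary=genes,
    )


def write_params(
    params: PredictionParams, stress_vocabulary: list[str], path
) -> None:
    pd.DataFrame(
        {"stress": stress_vocabulary, "a": params.a, "b": params.b}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_params(path) -> tuple[PredictionParams, list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in ("stress", "a", "b") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    params = PredictionParams(
        a=df["a"].astype(float).to_numpy(), b=df["b"].astype(float).to_numpy()
    )
    return params, df["stress"].tolist()


def write_ground_truth(truth, stress_vocabulary, gene_vocabulary, path) -> None:
    """Planted-truth TSV: gene, stress, direction, class in {specific, shared}."""
    rows = []
    for stress in stress_vocabulary:
        for gene, direction in truth.specific.get(stress, []):
            rows.append((gene_vocabulary[gene], stress, direction, "specific"))
    for gene, pair, dirs in truth.shared:
        for stress, direction in zip(pair, dirs):
            rows.append((gene_vocabulary[gene], stress, direction, "shared"))
    pd.DataFrame(
        rows, columns=["gene_id", "stress", "direction", "class"]
    ).to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration, merged over the defaults.

    Recognised keys: alpha, beta, fc_threshold, epochs_discovery,
    epochs_prediction, learning_rate, seed, top_k; a nested ``synthetic``
    mapping is passed through to :class:`~stressgenepred.simulate.SyntheticConfig`.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError:
        raw = json.loads(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(CONFIG_DEFAULTS) - {"synthetic", "n_test", "cmcl_variant"}
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    config = dict(CONFIG_DEFAULTS)
    config.update(raw)
    return config
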