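"""Table readers/writers, read-count normalization, feature extraction and
model checkpoints — the plumbing between the file formats and the model.

All tables are tab-separated with a header; genomic coordinates are 0-based
half-open throughout (1-based inputs are accepted behind an explicit flag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .descriptors import (DescriptorConfig, NormalizationStats,
                          raw_descriptor_matrix)
from .encoding import (SITE_LENGTH, SgRNATargetPair, encode_pair,
                       mismatch_count)
from .network import (NetworkConfig, OffTargetNetwork, TrainConfig,
                      TrainedModel)

CHECKPOINT_FORMAT = "guidepost-checkpoint-1"
DEFAULT_COUNT_CEILING = 10_000.0

REQUIRED_COLUMNS = ("sgrna_seq", "target_seq", "chrom", "start", "strand")


class TableParseError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


class CheckpointVersionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A site table plus the normalization constants applied to its counts."""

    records: pd.DataFrame
    per_guide_factors: Dict[str, float] = field(default_factory=dict)
    global_factor: float = 1.0
    ceiling: Optional[float] = None

    def pairs(self) -> List[SgRNATargetPair]:
        return table_to_pairs(self.records)

    def counts(self) -> np.ndarray:
        return self.records["read_count"].to_numpy(dtype=np.float64)


def read_site_table(path, one_based: bool = False) -> Dataset:
    """Read a tab-separated site table (header required).

    Required columns: sgrna_seq, target_seq, chrom, start, strand;
    read_count and any extra columns are carried through.  Sequence-length
    violations are reported with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing required columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        if len(str(row.sgrna_seq)) != SITE_LENGTH or len(str(row.target_seq)) != SITE_LENGTH:
            raise TableParseError(
                f"{path}: line {i}: sequences must be {SITE_LENGTH} nt")
    if one_based:
        df = df.copy()
        df["start"] = df["start"].astype(int) - 1
    if "read_count" in df.columns and (df["read_count"] < 0).any():
        raise TableParseError(f"{path}: negative read counts")
    return Dataset(records=df)


def write_site_table(dataset: Dataset, path) -> None:
    dataset.records.to_csv(path, sep="\t", index=False)


def table_to_pairs(df: pd.DataFrame) -> List[SgRNATargetPair]:
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(SgRNATargetPair(
            sgrna_seq=str(row.sgrna_seq),
            target_seq=str(row.target_seq),
            chrom=str(row.chrom),
            start=int(row.start),
            strand=str(row.strand),
            read_count=float(row.read_count) if hasattr(row, "read_count") else None,
            site_id=str(row.site_id) if hasattr(row, "site_id") else None,
        ))
    return pairs


def normalize_read_counts(dataset: Dataset, ceiling: float = DEFAULT_COUNT_CEILING) -> Dataset:
    """Two-step count normalization.

    Step 1 equalizes sequencing depth across guides: each guide's counts
    are multiplied by (mean per-guide total / this guide's total), so all
    per-guide totals become equal.  Step 2 linearly scales every count so
    the global maximum equals ``ceiling`` (10 000 by default).  Both
    factors are stored on the returned Dataset so the transformation is
    invertible.
    """
    df = dataset.records.copy()
    if "read_count" not in df.columns:
        raise NormalizationError("site table has no read_count column")
    counts = df["read_count"].to_numpy(dtype=np.float64)
    if not (counts > 0).any():
        raise NormalizationError("cannot normalize an all-zero dataset")
    guide_key = df["sgrna_seq"]
    totals = df.assign(_c=counts).groupby(guide_key)["_c"].sum()
    positive_totals = totals[totals > 0]
    target_total = positive_totals.mean()
    factors = {g: (target_total / t if t > 0 else 1.0) for g, t in totals.items()}
    scaled = counts * guide_key.map(factors).to_numpy()
    global_factor = ceiling / scaled.max()
    df["read_count"] = scaled * global_factor
    return Dataset(records=df, per_guide_factors=factors,
                   global_factor=global_factor, ceiling=ceiling)


def denormalize_counts(dataset: Dataset) -> np.ndarray:
    """Invert normalize_read_counts using the stored factors."""
    df = dataset.records
    factors = df["sgrna_seq"].map(dataset.per_guide_factors).to_numpy(dtype=np.float64)
    return df["read_count"].to_numpy(dtype=np.float64) / (factors * dataset.global_factor)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def load_genome(path) -> Dict[str, str]:
    """Load an (indexed) FASTA into an in-memory {contig: sequence} map."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


class Featurizer:
    """Maps site pairs to the (6x23, 4x23) feature arrays the network eats.

    Holds the genome, the descriptor configuration and the frozen
    normalization statistics; the statistics are fitted once on training
    sites and persisted with the model checkpoint.
    """

    def __init__(self, genome: Dict[str, str],
                 descriptor_config: Optional[DescriptorConfig] = None):
        self.genome = genome
        self.config = descriptor_config or DescriptorConfig()

    def fit_norm_stats(self, pairs: Sequence[SgRNATargetPair]) -> NormalizationStats:
        raws = [raw_descriptor_matrix(self.genome, p, self.config) for p in pairs]
        self.config.norm_stats = NormalizationStats.fit(raws)
        return self.config.norm_stats

    def features(self, pairs: Sequence[SgRNATargetPair]) -> Tuple[np.ndarray, np.ndarray]:
        if self.config.norm_stats is None:
            raise NormalizationError(
                "descriptor normalization statistics not fitted; call "
                "fit_norm_stats on training sites first")
        xs = np.stack([encode_pair(p).matrix for p in pairs])
        xp = np.stack([
            self.config.norm_stats.apply(raw_descriptor_matrix(self.genome, p, self.config))
            for p in pairs])
        return xs, xp


# ---------------------------------------------------------------------------
# Scoring output
# ---------------------------------------------------------------------------


def score_sites(model: TrainedModel, pairs: Sequence[SgRNATargetPair],
                featurizer: Featurizer, level: float = 0.95) -> pd.DataFrame:
    """Per-site parameter table: pi, mu, theta, mean, cv, ucb, mismatches."""
    from .distributions import ZINBParams, zinb_moments, zinb_ppf

    xs, xp = featurizer.features(pairs)
    params = model.predict_params(xs, xp)
    mean, _, cv = zinb_moments(params)
    ucb = zinb_ppf(level, params)
    scale = model.count_scale or 1.0
    return pd.DataFrame({
        "site_id": [p.site_id or f"site{i:06d}" for i, p in enumerate(pairs)],
        "pi": np.atleast_1d(params.pi),
        "mu": np.atleast_1d(params.mu),
        "theta": np.atleast_1d(params.theta),
        "mean": np.atleast_1d(mean) / scale,
        "cv": np.atleast_1d(cv),
        f"ucb{int(round(level * 100))}": np.atleast_1d(ucb) / scale,
        "mismatches": [mismatch_count(p) for p in pairs],
    })


def write_scores(path, scores: pd.DataFrame) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: TrainedModel, path) -> None:
    """Persist weights + config snapshot + normalization stats + metadata."""
    arrays = {f"net.{k}": v for k, v in model.network.state_arrays().items()}
    meta = {
        "format": CHECKPOINT_FORMAT,
        "head": model.head,
        "net_config": vars(model.net_config),
        "train_config": {**vars(model.train_config),
                         "split_fractions": list(model.train_config.split_fractions)},
        "norm_stats": model.norm_stats,
        "count_scale": model.count_scale,
        "metadata": model.metadata,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise CheckpointVersionError(
                f"unsupported checkpoint format {meta.get('format')!r}")
        net_config = NetworkConfig(**meta["net_config"])
        tc = dict(meta["train_config"])
        tc["split_fractions"] = tuple(tc["split_fractions"])
        train_config = TrainConfig(**tc)
        net = OffTargetNetwork(net_config, meta["head"], seed=meta["metadata"].get("seed", 0))
        state = {k[len("net."):]: npz[k] for k in npz.files if k.startswith("net.")}
        net.load_state_arrays(state)
        net.set_training(False)
    return TrainedModel(network=net, head=meta["head"], net_config=net_config,
                        train_config=train_config, norm_stats=meta["norm_stats"],
                        count_scale=meta["count_scale"], metadata=meta["metadata"])
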