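"""Fully synthetic genomes, site tables and ZINB-distributed read counts.

The generator emulates the sparsity structure of genome-wide off-target
cleavage assays: each guide has one perfectly matched on-target site with a
large expected read count and little zero inflation, and many off-target
sites whose negative-binomial mean decays multiplicatively with mismatch
count while the zero-inflation weight grows with it.  The mean is also
coupled to the GC content of the planted genomic context so that both the
sequence branch and the descriptor branch of the network carry recoverable
signal.  Ground-truth per-site parameters are emitted in a sidecar table,
which is what makes parameter-recovery and calibration assertions runnable
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .descriptors import FLANK, reverse_complement
from .distributions import ZINBParams, zinb_sample
from .encoding import SITE_LENGTH

_BASES = np.array(list("ACGT"))


class SimulationConfigError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``mu_on`` is the on-target NB mean on the normalized-count scale (the
    training pipeline caps the maximum count at 10 000); ``mean_decay`` is
    the per-mismatch multiplicative decay of the mean;
    ``zero_inflation_base`` is the on-target zero-inflation weight, which
    rises with mismatch count on the logit scale with slope
    ``pi_mismatch_slope``.  ``gc_coupling`` doubles (halves) the mean per
    +0.5 (-0.5) deviation of context GC from 0.5 when set to 2.0.
    """

    n_guides: int = 20
    sites_per_guide: int = 100
    genome_length: int = 200_000
    zero_inflation_base: float = 0.05
    pi_mismatch_slope: float = 0.7
    mean_decay: float = 0.4
    mu_on: float = 2000.0
    theta_true: float = 0.7
    gc_coupling: float = 2.0
    max_mismatches: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.zero_inflation_base <= 1.0):
            raise SimulationConfigError("zero_inflation_base must be in [0,1]")
        if not (0.0 < self.mean_decay <= 1.0):
            raise SimulationConfigError("mean_decay must be in (0,1]")
        if min(self.n_guides, self.sites_per_guide, self.genome_length) <= 0:
            raise SimulationConfigError("sizes must be positive")


def simulate_genome(length: int, seed: int) -> str:
    """Uniform random A/C/G/T contig, reproducible from the seed."""
    if length < FLANK * 2 + SITE_LENGTH:
        raise SimulationConfigError(
            f"genome length must be >= {FLANK * 2 + SITE_LENGTH}")
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def write_fasta(sequence: str, path, name: str = "chrSim", width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def simulate_sites(
    spec: SyntheticSpec,
    genome: Optional[str] = None,
    chrom: str = "chrSim",
) -> Tuple[str, pd.DataFrame, pd.DataFrame]:
    """Plant guide sites into a genome and sample their read counts.

    Returns ``(genome, site_table, sidecar)``.  The site table has the
    standard columns (sgrna_seq, target_seq, chrom, start, strand,
    read_count) plus site_id/guide_id; the sidecar carries the hidden truth
    (pi_true, mu_true, theta_true, mismatches, dropped_flag).
    """
    rng = np.random.default_rng(spec.seed)
    n_sites = spec.n_guides * (1 + spec.sites_per_guide)
    margin = FLANK + 1
    spacing = SITE_LENGTH + 7
    needed = 2 * margin + n_sites * spacing
    if genome is None:
        length = max(spec.genome_length, needed)
        genome_arr = np.array(list(simulate_genome(length, spec.seed)))
    else:
        if len(genome) < needed:
            raise SimulationConfigError(
                f"genome too short for {n_sites} sites: need {needed}, got {len(genome)}")
        genome_arr = np.array(list(genome.upper()))

    # Non-overlapping loci in planting order, then shuffled.
    starts = margin + spacing * rng.permutation(n_sites)

    rows = []
    truth = []
    site_idx = 0
    for g in range(spec.n_guides):
        sgrna = "".join(_BASES[rng.integers(0, 4, size=SITE_LENGTH)])
        for k in range(1 + spec.sites_per_guide):
            m = 0 if k == 0 else int(rng.integers(1, spec.max_mismatches + 1))
            target = list(sgrna)
            if m:
                pos = rng.choice(SITE_LENGTH, size=m, replace=False)
                for p in pos:
                    choices = [b for b in "ACGT" if b != target[p]]
                    target[p] = choices[rng.integers(0, 3)]
            target = "".join(target)
            start = int(starts[site_idx])
            strand = "+" if rng.random() < 0.5 else "-"
            planted = target if strand == "+" else reverse_complement(target)
            genome_arr[start:start + SITE_LENGTH] = list(planted)
            rows.append({
                "site_id": f"g{g:03d}s{k:04d}",
                "guide_id": f"g{g:03d}",
                "sgrna_seq": sgrna,
                "target_seq": target,
                "chrom": chrom,
                "start": start,
                "strand": strand,
                "mismatches": m,
            })
            site_idx += 1

    # Context GC from the final genome (after planting), center of the site.
    genome_str = "".join(genome_arr)
    gc_mask = np.isin(genome_arr, ["G", "C"]).astype(np.float64)
    cs = np.concatenate([[0.0], np.cumsum(gc_mask)])
    for row in rows:
        center = row["start"] + SITE_LENGTH // 2
        lo, hi = center - FLANK, center + FLANK + 1
        gc = (cs[hi] - cs[lo]) / (hi - lo)
        m = row["mismatches"]
        mu = spec.mu_on * spec.mean_decay ** m * spec.gc_coupling ** (2 * (gc - 0.5))
        pi = _logistic(_logit(spec.zero_inflation_base) + spec.pi_mismatch_slope * m)
        truth.append({
            "site_id": row["site_id"],
            "pi_true": pi,
            "mu_true": mu,
            "theta_true": spec.theta_true,
            "mismatches": m,
            "context_gc": gc,
            "dropped_flag": 0,
        })

    sidecar = pd.DataFrame(truth)
    params = ZINBParams(sidecar["pi_true"].to_numpy(),
                        sidecar["mu_true"].to_numpy(),
                        np.full(len(sidecar), spec.theta_true))
    counts = zinb_sample(params, 1, seed=spec.seed + 10_000)[0]
    table = pd.DataFrame(rows)
    table["read_count"] = counts.astype(np.float64)
    table = table[["site_id", "guide_id", "sgrna_seq", "target_seq",
                   "chrom", "start", "strand", "mismatches", "read_count"]]
    return genome_str, table, sidecar


def corrupt_with_technical_zeros(
    table: pd.DataFrame,
    extra_dropout: float,
    seed: int,
    sidecar: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Independently zero each positive count with probability extra_dropout.

    Models assay-sensitivity dropout (active sites recorded as zeros).
    Returns the corrupted table and the boolean mask of newly zeroed rows;
    if a sidecar is given its ``dropped_flag`` column is set on a copy and
    modified in place of the returned mask semantics.
    """
    if not (0.0 <= extra_dropout < 1.0):
        raise SimulationConfigError("extra_dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    positive = out["read_count"].to_numpy() > 0
    dropped = positive & (rng.random(len(out)) < extra_dropout)
    out.loc[dropped, "read_count"] = 0.0
    if sidecar is not None:
        sidecar.loc[dropped, "dropped_flag"] = 1
    return out, dropped
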