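"""Synthetic pooled-screen generation: counts and sequencing reads.

The generative model mirrors how a survival screen produces data.  Each pool
carries a skewed baseline representation of its constructs (log-normal
abundances — pooled libraries are never uniform).  Reference-arm replicates
sequence that baseline; treated-arm replicates sequence the baseline reweighted
by each construct's selection effect on the log2 scale (a hairpin with effect
+1 doubles its relative abundance under treatment).  Replicate counts are
negative-binomial draws around the expected representation at the sample's
sequencing depth, with dispersion phi (variance mu + phi*mu^2; phi=0 recovers
Poisson).  FASTQ emission writes one read per counted molecule with the
barcode at a fixed offset inside the construct scaffold, plus a configurable
fraction of unassignable spike-in reads standing in for the phiX fraction of a
real run, and optional per-base substitution noise.

Everything is bit-reproducible given (config, seed): every sample draws from a
generator seeded by a (seed, pool, arm, replicate) tuple, so results do not
depend on evaluation order.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import FLANK_5P, LibraryDesign, construct_sequence
from .quantify import BarcodeIndex, CountMatrix

__all__ = [
    "SimulationConfig",
    "EffectProfile",
    "simulate_screen_counts",
    "emit_fastq",
    "load_simulation_config",
]

_ARM_CODE = {"reference": 0, "treated": 1}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the screen generator.

    sequencing_depth is the expected number of barcode-derived reads per
    sample; spike_in_fraction is the fraction of the final read pool that is
    unassignable (phiX stand-in); dispersion is the negative-binomial phi.
    """

    n_replicates_per_arm: int = 3
    sequencing_depth: float = 100_000.0
    dispersion: float = 0.1
    abundance_sigma: float = 0.5
    spike_in_fraction: float = 0.10
    read_length: int = 75
    error_rate: float = 0.0
    barcode_offset: int = len(FLANK_5P)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates_per_arm < 1:
            raise ValueError("n_replicates_per_arm must be >= 1")
        if self.sequencing_depth < 0:
            raise ValueError("sequencing_depth must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.spike_in_fraction < 1:
            raise ValueError("spike_in_fraction must be in [0, 1)")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML or TOML file mirroring field names."""
    path = Path(path)
    if path.suffix in (".toml",):
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
    return SimulationConfig(**data)


@dataclass
class EffectProfile:
    """Per-shRNA true selection effect on the log2 scale.

    0 = neutral; positive = enriched under treatment (knockdown protects);
    negative = depleted.  Every construct in the library has exactly one value.
    """

    effects: pd.Series  # index shrna_id, float

    @classmethod
    def neutral(cls, design: LibraryDesign) -> "EffectProfile":
        idx = pd.Index(design.constructs["shrna_id"])
        return cls(pd.Series(0.0, index=idx))

    @classmethod
    def from_gene_effects(
        cls,
        design: LibraryDesign,
        gene_effects: Mapping[str, float],
        n_affected: int | None = None,
        shrna_overrides: Mapping[str, float] | None = None,
    ) -> "EffectProfile":
        """Map gene-level planted effects onto member shRNAs.

        By default all of a gene's constructs receive the gene effect; with
        ``n_affected`` only the first n (in library order) do.  Per-shRNA
        overrides are applied last.
        """
        df = design.constructs
        effects = pd.Series(0.0, index=pd.Index(df["shrna_id"]))
        unknown = set(gene_effects) - set(df["gene_id"])
        if unknown:
            raise KeyError(f"genes not in library: {sorted(unknown)}")
        for gene, eff in gene_effects.items():
            members = df.loc[df["gene_id"] == gene, "shrna_id"]
            if n_affected is not None:
                members = members.iloc[:n_affected]
            effects.loc[members] = float(eff)
        if shrna_overrides:
            for sid, eff in shrna_overrides.items():
                if sid not in effects.index:
                    raise KeyError(f"shRNA not in library: {sid}")
                effects.loc[sid] = float(eff)
        return cls(effects)

    def validate_against(self, design: LibraryDesign) -> None:
        lib = pd.Index(design.constructs["shrna_id"])
        if not lib.isin(self.effects.index).all():
            missing = lib.difference(self.effects.index)
            raise ValueError(f"effects missing for shRNAs: {list(missing[:5])}...")


def _sample_rng(seed: int, pool: int, arm: str, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, pool, _ARM_CODE[arm], replicate])
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    lam = np.where(mean > 0, rng.gamma(1.0 / phi, phi * mean), 0.0)
    return rng.poisson(lam)


def simulate_screen_counts(
    design: LibraryDesign,
    effects: EffectProfile,
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix]:
    """Simulate a screen: (reference arm, treated arm) count matrices.

    Each matrix spans the whole library with one block of columns per pool;
    counts outside a column's own pool are structurally zero.  Within a pool,
    a shared log-normal baseline representation is drawn once, the treated arm
    reweights it by 2**effect, and each replicate's counts are NB draws with
    per-construct mean proportional to representation scaled to
    ``sequencing_depth``.
    """
    if len(design) == 0:
        raise ValueError("empty library design")
    effects.validate_against(design)

    all_rows = pd.Index(design.constructs["shrna_id"])
    arm_frames: dict[str, list[pd.DataFrame]] = {"reference": [], "treated": []}
    arm_meta: dict[str, dict[str, list]] = {
        arm: {"sample_id": [], "pool": [], "condition": [], "replicate": []}
        for arm in ("reference", "treated")
    }
    pools = sorted(design.constructs["pool"].unique())
    for pool in pools:
        block = design.pool_constructs(pool)
        sids = pd.Index(block["shrna_id"])
        base_rng = np.random.default_rng(np.random.SeedSequence([config.seed, pool, 2, 0]))
        baseline = base_rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(sids))
        eff = effects.effects.loc[sids].to_numpy()
        weights = {"reference": baseline, "treated": baseline * np.exp2(eff)}
        for arm, w in weights.items():
            props = w / w.sum()
            cols = {}
            for rep in range(1, config.n_replicates_per_arm + 1):
                rng = _sample_rng(config.seed, pool, arm, rep)
                sid = f"pool{pool}_{arm}_rep{rep}"
                cols[sid] = _nb_draw(rng, config.sequencing_depth * props, config.dispersion).astype(int)
                arm_meta[arm]["sample_id"].append(sid)
                arm_meta[arm]["pool"].append(pool)
                arm_meta[arm]["condition"].append(arm)
                arm_meta[arm]["replicate"].append(rep)
            arm_frames[arm].append(
                pd.DataFrame(cols, index=sids).reindex(all_rows, fill_value=0)
            )

    def build(arm: str) -> CountMatrix:
        counts = pd.concat(arm_frames[arm], axis=1)
        meta = arm_meta[arm]
        samples = pd.DataFrame(
            {
                "pool": meta["pool"],
                "condition": meta["condition"],
                "replicate": meta["replicate"],
            },
            index=pd.Index(meta["sample_id"], name="sample_id"),
        )
        samples["unassigned_reads"] = 0
        samples["total_reads"] = counts[samples.index].sum(axis=0).astype(int)
        return CountMatrix(counts, samples)

    return build("reference"), build("treated")


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BYTE_TO_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_CODE[_b] = _i


def _encode_seq(seq: str) -> np.ndarray:
    return _BYTE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def emit_fastq(
    sample_counts: pd.Series,
    design: LibraryDesign,
    pool_index: int,
    config: SimulationConfig,
    path: str | Path,
    sample_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Write one sample's reads as FASTQ (gzip when path ends in .gz).

    One read per counted molecule: the construct scaffold with the barcode at
    offset ``config.barcode_offset``, padded to ``read_length``.  Additionally
    ``ceil(f/(1-f) * assigned)`` spike-in reads (f = spike_in_fraction) are
    emitted whose barcode window is guaranteed unassignable (at Hamming
    distance >= 2 from every library barcode).  Substitution errors are applied
    at ``error_rate`` per base.  Read order is shuffled.  Returns the number of
    reads written.
    """
    L = design.barcode_length
    if config.read_length < config.barcode_offset + L:
        raise ValueError(
            f"read_length {config.read_length} < barcode_offset + barcode_length "
            f"({config.barcode_offset + L})"
        )
    block = design.pool_constructs(pool_index)
    counts = sample_counts.reindex(block["shrna_id"], fill_value=0).astype(int)
    if (counts < 0).any():
        raise ValueError("negative counts")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, pool_index, 3, 0]))
    if sample_id is None:
        sample_id = str(Path(path).name).removesuffix(".gz").removesuffix(".fastq")

    n_assigned = int(counts.sum())
    f = config.spike_in_fraction
    n_spike = math.ceil(f / (1 - f) * n_assigned) if f > 0 else 0
    n_total = n_assigned + n_spike

    reads = np.empty((n_total, config.read_length), dtype=np.uint8)
    if n_assigned:
        templates = np.stack(
            [
                _encode_seq(construct_sequence(bc, config.read_length))
                for bc in block["barcode"]
            ]
        )
        reads[:n_assigned] = np.repeat(templates, counts.to_numpy(), axis=0)
    if n_spike:
        index = BarcodeIndex(block["barcode"].tolist(), block["shrna_id"].tolist(), 0)
        off = config.barcode_offset
        filled = 0
        while filled < n_spike:
            cand = rng.integers(0, 4, size=(n_spike - filled, config.read_length), dtype=np.uint8)
            for row in cand:
                window = bytes(_BASE_BYTES[row[off : off + L]]).decode()
                if index.is_near(window):
                    continue  # astronomically rare; keeps round-trip exact
                reads[n_assigned + filled] = row
                filled += 1
                if filled == n_spike:
                    break
    if config.error_rate > 0 and n_total:
        err = rng.random(reads.shape) < config.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        reads[err] = (reads[err] + shift) % 4

    order = rng.permutation(n_total)
    reads = reads[order]
    qual = "I" * config.read_length
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for i in range(n_total):
            seq = bytes(_BASE_BYTES[reads[i]]).decode()
            out.write(f"@{sample_id}:{i}\n{seq}\n+\n{qual}\n")
    return n_total
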