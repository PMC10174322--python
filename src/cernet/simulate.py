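"""Synthetic three-layer RNA-seq datasets with planted ground truth.

Emulates the statistical structure a ceRNA (competing endogenous RNA)
analysis assumes: a small two-group case/control design with
negative-binomial counts per RNA layer (lncRNA, miRNA, mRNA), a subset of
features carrying a planted group fold change, a set of planted
lncRNA-miRNA-mRNA triplets coupled through a latent per-sample factor
(miRNA anti-correlated with both partners, lncRNA and mRNA positively
correlated), and transcript sequences carrying exact seed-complementary
miRNA binding sites at recorded positions.

Every stage draws from its own RNG substream derived from ``config.seed``
by a fixed offset, so enlarging one layer never reshuffles the draws of
another and identical seeds give byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from .containers import GROUP_A, GROUP_B, CountMatrix

LAYERS = ("lnc", "mirna", "mrna")

RNA_ALPHABET = "ACGU"
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

# fixed substream offsets; appending stages must not renumber earlier ones
_STREAM = {"counts_lnc": 1, "counts_mirna": 2, "counts_mrna": 3,
           "triplets": 4, "sequences": 5, "annotation": 6}

MIRNA_LENGTH = 22
SEED_SITE_LEN = 8
# spacing between consecutive planted sites (nt between site end and next
# start); sponge MREs cluster, so gaps are tens of nt, not transcript-wide
_MIN_SITE_GAP = 10
_MAX_SITE_GAP = 50


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig cannot produce a valid dataset."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults emulate the small clinical two-group design this kind of
    tissue study uses (4 cases vs 4 controls) at a desk-scale feature
    census; the negative-binomial dispersion follows the trend
    ``alpha(mu) = a0 + a1/mu``.
    """

    n_per_group: int = 4
    n_lnc: int = 150
    n_mi: int = 60
    n_mrna: int = 300
    frac_de: float = 0.15          # fraction of features per layer with planted DE
    lfc_mean: float = 2.0          # mean of planted |log2 fold change|
    lfc_sd: float = 0.5
    dispersion_a0: float = 0.05    # asymptotic dispersion
    dispersion_a1: float = 2.0     # 1/mu dispersion term
    n_triplets: int = 20
    coupling: float = 0.8          # latent-factor strength, log2 amplitude = 2*coupling
    seed: int = 0
    seq_len_range: tuple[int, int] = (300, 800)
    site_per_pair: int = 3         # planted seed sites per (miRNA, transcript) pair

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ConfigurationError("n_per_group must be >= 3")
        if min(self.n_lnc, self.n_mi, self.n_mrna) <= 0:
            raise ConfigurationError("layer sizes must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigurationError("frac_de must lie in [0, 1]")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ConfigurationError("dispersion coefficients must be >= 0")
        if not 0.0 < self.coupling <= 1.0:
            raise ConfigurationError("coupling must lie in (0, 1]")
        if self.n_triplets < 0:
            raise ConfigurationError("n_triplets must be >= 0")
        if self.n_triplets > min(self.n_lnc, self.n_mi, self.n_mrna):
            raise ConfigurationError("n_triplets exceeds smallest layer")
        lo, hi = self.seq_len_range
        if not 0 < lo <= hi:
            raise ConfigurationError("invalid seq_len_range")
        if self.site_per_pair < 1:
            raise ConfigurationError("site_per_pair must be >= 1")
        # planted sites form a cluster; the worst-case footprint must fit
        footprint = SEED_SITE_LEN * self.site_per_pair + _MAX_SITE_GAP * (self.site_per_pair - 1)
        if lo < footprint:
            raise ConfigurationError(
                "transcripts too short for requested non-overlapping sites"
            )

    def stream(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stage]])


@dataclass
class PlantedSite:
    mirna_id: str
    transcript_id: str
    start: int              # 0-based on the transcript, 5'->3'
    seed_class: str

    def as_tuple(self):
        return (self.mirna_id, self.transcript_id, self.start, self.seed_class)


@dataclass
class PlantedTruth:
    """The generator's record of what it planted."""

    de: dict[str, dict[str, float]] = field(
        default_factory=lambda: {layer: {} for layer in LAYERS}
    )  # layer -> feature id -> true log2FC (B vs A)
    triplets: list[tuple[str, str, str]] = field(default_factory=list)
    planted_sites: list[PlantedSite] = field(default_factory=list)

    def de_ids(self, layer: str) -> set[str]:
        return set(self.de[layer])

    def triplet_pairs(self) -> set[tuple[str, str]]:
        """Planted (lncRNA, mRNA) partner pairs."""
        return {(l, g) for l, _, g in self.triplets}


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    counts: dict[str, CountMatrix]
    transcripts: dict[str, str]    # lncRNA + mRNA sequences, 5'->3'
    mirnas: dict[str, str]
    annotation: list               # TranscriptRecord list
    truth: PlantedTruth


# ------------------------------------------------------------------ counts

def _layer_ids(layer: str, n: int) -> list[str]:
    prefix = {"lnc": "LNC", "mirna": "MIR", "mrna": "MRNA"}[layer]
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


def _sample_frame(config: SyntheticConfig) -> tuple[list[str], pd.Series, np.ndarray]:
    n = config.n_per_group
    samples = [f"SR{i+1}" for i in range(n)] + [f"AF{i+1}" for i in range(n)]
    groups = pd.Series([GROUP_A] * n + [GROUP_B] * n, index=samples, name="group")
    x = np.array([0] * n + [1] * n)
    return samples, groups, x


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion alpha): variance = mu + alpha*mu^2; Poisson at alpha=0."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / alpha[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def generate_counts(config: SyntheticConfig) -> tuple[dict[str, CountMatrix], PlantedTruth]:
    """Draw NB count matrices for the three layers with planted fold changes.

    Counts are NB with mean ``s_j * q_g * 2^(beta_g * x_j)`` where ``x_j``
    indicates the case group, ``beta_g`` is zero for non-DE features, the
    per-sample size factors ``s_j`` are log-uniform in [0.5, 2] and the
    dispersion follows the configured trend evaluated at the baseline
    ``q_g``.
    """
    samples, groups, x = _sample_frame(config)
    sizes = {"lnc": config.n_lnc, "mirna": config.n_mi, "mrna": config.n_mrna}
    truth = PlantedTruth()
    layers: dict[str, CountMatrix] = {}
    for layer in LAYERS:
        rng = config.stream(f"counts_{layer}")
        n = sizes[layer]
        ids = _layer_ids(layer, n)
        q = np.exp(rng.uniform(np.log(100.0), np.log(3000.0), size=n))
        s = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))
        n_de = int(round(config.frac_de * n))
        de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
        beta = np.zeros(n)
        if n_de:
            mag = np.abs(rng.normal(config.lfc_mean, config.lfc_sd, size=n_de))
            sign = rng.choice([-1.0, 1.0], size=n_de)
            beta[de_idx] = sign * mag
        mean = s[None, :] * q[:, None] * np.power(2.0, beta[:, None] * x[None, :])
        alpha = config.dispersion_a0 + config.dispersion_a1 / q
        counts = _nb_draw(rng, mean, alpha[:, None])
        cm = CountMatrix(
            pd.DataFrame(counts, index=ids, columns=samples),
            groups,
            mean_model=pd.DataFrame(mean, index=ids, columns=samples),
        )
        layers[layer] = cm
        truth.de[layer] = {ids[i]: float(beta[i]) for i in sorted(de_idx)}
    return layers, truth


# ---------------------------------------------------------------- triplets

def generate_triplets(
    config: SyntheticConfig, layers: dict[str, CountMatrix]
) -> tuple[dict[str, CountMatrix], PlantedTruth]:
    """Plant ceRNA triplets by redrawing member counts with a shared factor.

    For each triplet a latent standard-normal per-sample factor ``z_j``
    multiplies the expected counts of the lncRNA and mRNA members by
    ``2^(A z_j)`` and of the miRNA member by ``2^(-A z_j)``, with amplitude
    ``A = 2 * coupling`` (log2 units). This induces the ceRNA sign
    pattern: miRNA negatively correlated with both partners, partners
    positively correlated, with magnitude increasing in ``coupling``.
    Feature ids are used by at most one triplet. Returns the modified
    layers and a truth record holding the triplet memberships.
    """
    truth = PlantedTruth()
    if config.n_triplets == 0:
        return layers, truth
    for layer in LAYERS:
        if layers[layer].mean_model is None:
            raise ConfigurationError("triplet planting requires generator count layers")
    rng = config.stream("triplets")
    members = {}
    for layer in LAYERS:
        ids = layers[layer].gene_ids
        if config.n_triplets > len(ids):
            raise ConfigurationError("n_triplets exceeds layer size")
        members[layer] = [ids[i] for i in rng.choice(len(ids), config.n_triplets,
                                                     replace=False)]
    amp = 2.0 * config.coupling
    n_samples = len(layers["lnc"].sample_ids)
    out: dict[str, CountMatrix] = {}
    factors: dict[str, dict[str, np.ndarray]] = {layer: {} for layer in LAYERS}
    for t in range(config.n_triplets):
        z = rng.normal(size=n_samples)
        factors["lnc"][members["lnc"][t]] = np.power(2.0, amp * z)
        factors["mrna"][members["mrna"][t]] = np.power(2.0, amp * z)
        factors["mirna"][members["mirna"][t]] = np.power(2.0, -amp * z)
    for layer in LAYERS:
        cm = layers[layer]
        counts = cm.counts.copy()
        means = cm.mean_model.copy()
        q_proxy = cm.mean_model.mean(axis=1)
        alpha = config.dispersion_a0 + config.dispersion_a1 / q_proxy
        for gid, f in factors[layer].items():
            mu = cm.mean_model.loc[gid].to_numpy() * f
            counts.loc[gid] = _nb_draw(rng, mu, np.full(n_samples, alpha[gid]))
            means.loc[gid] = mu
        out[layer] = CountMatrix(counts, cm.groups, mean_model=means)
    truth.triplets = list(zip(members["lnc"], members["mirna"], members["mrna"]))
    return out, truth


# --------------------------------------------------------------- sequences

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA_ALPHABET), size=length))


def _place_sites(rng: np.random.Generator, seq_len: int, k: int) -> list[int]:
    """Start positions of a cluster of k non-overlapping 8-nt sites.

    Consecutive sites are separated by a gap drawn uniformly from
    [10, 50] nt, emulating the clustered response elements of miRNA
    sponges; the cluster itself starts at a uniform random offset.
    """
    gaps = rng.integers(_MIN_SITE_GAP, _MAX_SITE_GAP + 1, size=max(0, k - 1))
    footprint = SEED_SITE_LEN * k + int(gaps.sum())
    if footprint > seq_len:
        raise ConfigurationError("transcript too short for requested sites")
    p0 = int(rng.integers(0, seq_len - footprint + 1))
    starts = [p0]
    for g in gaps:
        starts.append(starts[-1] + SEED_SITE_LEN + int(g))
    return starts


def generate_sequences(
    config: SyntheticConfig, truth: PlantedTruth
) -> tuple[dict[str, str], dict[str, str], PlantedTruth]:
    """Random-background transcripts with exact seed sites planted.

    Transcripts (all lncRNAs and mRNAs) are uniform A/C/G/U at lengths
    drawn from ``seq_len_range``; miRNAs are 22 nt starting with U (the
    overwhelmingly most common 5' residue of mature miRNAs, and the choice
    that makes a planted perfect site an 8mer: an A faces miRNA position
    1). For every planted triplet, ``site_per_pair`` copies of the exact
    reverse complement of miRNA positions 1-8 overwrite the background at
    recorded non-overlapping positions on both partner transcripts. Decoy
    transcripts receive no planted sites.
    """
    rng = config.stream("sequences")
    mirna_ids = _layer_ids("mirna", config.n_mi)
    mirnas = {mid: "U" + _random_seq(rng, MIRNA_LENGTH - 1) for mid in mirna_ids}
    lo, hi = config.seq_len_range
    transcripts: dict[str, str] = {}
    for tid in _layer_ids("lnc", config.n_lnc) + _layer_ids("mrna", config.n_mrna):
        transcripts[tid] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
    new_truth = dataclasses.replace(truth, planted_sites=[])
    for lnc_id, mi_id, mrna_id in truth.triplets:
        site = revcomp(mirnas[mi_id][:SEED_SITE_LEN])
        for tid in (lnc_id, mrna_id):
            seq = transcripts[tid]
            for p in _place_sites(rng, len(seq), config.site_per_pair):
                seq = seq[:p] + site + seq[p + SEED_SITE_LEN:]
                new_truth.planted_sites.append(
                    PlantedSite(mi_id, tid, p, "8mer")
                )
            transcripts[tid] = seq
    return transcripts, mirnas, new_truth


# -------------------------------------------------------------- annotation

_CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


def generate_annotation(config: SyntheticConfig, transcripts: dict[str, str]) -> list:
    """Plumbing records (random loci) matching the generated transcripts."""
    from .catalog import TranscriptRecord

    rng = config.stream("annotation")
    records = []
    for tid, seq in transcripts.items():
        is_lnc = tid.startswith("LNC")
        start = int(rng.integers(1, 10_000_000))
        records.append(TranscriptRecord(
            id=tid,
            chrom=str(rng.choice(_CHROMS)),
            strand=str(rng.choice(["+", "-"])),
            start=start,
            end=start + len(seq) - 1,
            exon_count=int(rng.integers(2, 12)),
            biotype="lncRNA_candidate" if is_lnc else "protein_coding",
            length=len(seq),
            annotated=False,
        ))
    return records


# ------------------------------------------------------------ orchestration

def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full dataset: counts, triplet structure, sequences, annotation, truth."""
    layers, truth = generate_counts(config)
    layers, trip_truth = generate_triplets(config, layers)
    truth.triplets = trip_truth.triplets
    transcripts, mirnas, truth = generate_sequences(config, truth)
    annotation = generate_annotation(config, transcripts)
    return SyntheticDataset(config, layers, transcripts, mirnas, annotation, truth)


# -------------------------------------------------------------- round trip

_COUNT_FILES = {layer: f"counts_{layer}.tsv" for layer in LAYERS}


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike) -> list[str]:
    """Write the dataset as plain text; returns the file names written."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    written = []
    for layer, fname in _COUNT_FILES.items():
        cio.write_counts_tsv(ds.counts[layer], os.path.join(outdir, fname))
        written.append(fname)
    cio.write_fasta(ds.transcripts, os.path.join(outdir, "transcripts.fa"))
    cio.write_fasta(ds.mirnas, os.path.join(outdir, "mirnas.fa"))
    cio.write_annotation_tsv(ds.annotation, os.path.join(outdir, "annotation.tsv"))
    truth_payload = {
        "config": dataclasses.asdict(ds.config),
        "de": ds.truth.de,
        "triplets": [list(t) for t in ds.truth.triplets],
        "planted_sites": [list(s.as_tuple()) for s in ds.truth.planted_sites],
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)
    written += ["transcripts.fa", "mirnas.fa", "annotation.tsv", "truth.json"]
    return written


def read_dataset(indir: str | os.PathLike) -> SyntheticDataset:
    indir = os.fspath(indir)
    with open(os.path.join(indir, "truth.json")) as fh:
        payload = json.load(fh)
    cfg_d = payload["config"]
    cfg_d["seq_len_range"] = tuple(cfg_d["seq_len_range"])
    config = SyntheticConfig(**cfg_d)
    counts = {layer: cio.read_counts_tsv(os.path.join(indir, fname))
              for layer, fname in _COUNT_FILES.items()}
    truth = PlantedTruth(
        de={layer: dict(payload["de"][layer]) for layer in LAYERS},
        triplets=[tuple(t) for t in payload["triplets"]],
        planted_sites=[PlantedSite(*s) for s in payload["planted_sites"]],
    )
    return SyntheticDataset(
        config=config,
        counts=counts,
        transcripts=cio.read_fasta(os.path.join(indir, "transcripts.fa")),
        mirnas=cio.read_fasta(os.path.join(indir, "mirnas.fa")),
        annotation=cio.read_annotation_tsv(os.path.join(indir, "annotation.tsv")),
        truth=truth,
    )
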