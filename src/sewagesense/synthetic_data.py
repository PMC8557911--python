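"""Synthetic river-survey generator with known ground truth.

Emulates a basin survey in which water samples from ``n_sites`` sites on
``n_dates`` dates are 16S-amplicon sequenced and assayed for the human
*Bacteroides* (HB) qPCR marker.  Each sample is a mixture of a
freshwater-plus-terrestrial background community and a sewage community,
combined according to a per-sample sewage volumetric fraction ``f``:

* ``f`` is drawn log-normally (truncated below 1) per sample;
* per-sample sewage and river total cell concentrations and the sewage HB
  concentration are drawn log-normally;
* the sewage read fraction ``r`` follows from ``f`` and the cell
  concentrations via the composition-form mass balance, and reads are drawn
  multinomially at a fixed depth;
* the true HB concentration is ``f x C_sewage,HB``, observed through
  multiplicative log-normal measurement noise and LOD/LOQ censoring.

Everything is a pure function of (config, seed): identical configs give
bit-identical bundles.  The generator produces dereplicated ASVs directly and
does not simulate raw reads, PCR/sequencing error, or chimeras.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hb_quantification import LOQ_CN_PER_100ML, StandardCurve
from .mass_balance import LogNormalSpec, sewage_read_fraction
from .source_partition import ASVTable, SourceDatabase, SourceRecord, write_source_fasta

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_reference_databases",
    "generate_river_samples",
    "generate_hb_measurements",
    "generate_bundle",
    "write_bundle",
    "load_config",
]

# true per-ASV source label -> partition category it should be recovered as
TRUE_CATEGORY = {
    "freshwater": "freshwater",
    "human_stool": "human_fecal",
    "sewer": "sewer",
    "terrestrial": "uncategorized",
}

# curve used to synthesize Cq observations (efficiency ~98%, typical intercept)
DEFAULT_SYNTHETIC_CURVE = StandardCurve(slope=-3.368, intercept=38.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and distributional parameters for one synthetic survey.

    Defaults emulate the survey design this generator targets: 16 sites
    sampled on 5 dates, ~50,000 reads per sample, 370-bp amplicons, and a
    sewage-fraction distribution whose induced sewage read fractions span
    roughly 0.3%-30% across samples.
    """

    n_sites: int = 16
    n_dates: int = 5
    urban_fraction: float = 0.5
    n_freshwater_refs: int = 150
    n_sewer_refs: int = 100
    n_stool_refs: int = 30
    n_terrestrial_asvs: int = 80
    amplicon_length: int = 370
    # None means a pollution-free basin: f = 0 for every sample
    sewage_fraction_spec: LogNormalSpec | None = field(
        default_factory=lambda: LogNormalSpec(3e-4, 4.0))
    depth_per_sample: int = 50_000
    hb_noise_gsd: float = 1.3
    seed: int = 0
    # distributional inputs shared with the mass-balance model
    c_sewage_hb: LogNormalSpec = field(default_factory=lambda: LogNormalSpec(7.8e6, 2.0))
    c_sewage_cells: LogNormalSpec = field(default_factory=lambda: LogNormalSpec(1e11, 2.0))
    c_river_cells: LogNormalSpec = field(default_factory=lambda: LogNormalSpec(1e9, 5.0))
    # sewage_p95 values for sewer/stool references: log-uniform over this range
    sewage_p95_range: tuple[float, float] = (1e-4, 1e-1)
    truncate_f: float | None = 0.99
    dirichlet_overdispersion: float | None = None
    lod_cn_100ml: float = LOQ_CN_PER_100ML / 2.0
    loq_cn_100ml: float = LOQ_CN_PER_100ML

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_dates < 1:
            raise ValueError("n_sites and n_dates must be >= 1")
        for name in ("n_freshwater_refs", "n_sewer_refs", "n_stool_refs",
                     "n_terrestrial_asvs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.urban_fraction <= 1:
            raise ValueError("urban_fraction must lie in [0, 1]")
        if self.depth_per_sample < 100:
            raise ValueError("depth_per_sample must be >= 100")
        if self.amplicon_length < 50:
            raise ValueError("amplicon_length < 50 is too short for exact matching")
        if self.hb_noise_gsd < 1:
            raise ValueError("hb_noise_gsd must be >= 1")
        lo, hi = self.sewage_p95_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("sewage_p95_range must satisfy 0 < lo <= hi <= 1")
        if self.truncate_f is not None and not (0 < self.truncate_f < 1):
            raise ValueError("truncate_f must lie in (0, 1)")
        if self.truncate_f is None and self.sewage_fraction_spec is not None:
            spec = self.sewage_fraction_spec
            if spec.geometric_sd > 1 or spec.geometric_mean >= 1:
                raise ValueError(
                    "sewage_fraction_spec can produce f >= 1; enable truncation"
                )

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.n_dates


@dataclass
class GroundTruth:
    """Known truth for one synthetic bundle.

    ``f`` is the per-sample sewage volumetric fraction; ``r_true`` the implied
    sewage read fraction (composition form); ``hb_true`` the uncensored
    per-sample HB concentration in CN/100 ml; ``asv_source`` the per-ASV true
    source label (freshwater / sewer / human_stool / terrestrial).
    """

    f: pd.Series
    r_true: pd.Series
    hb_true: pd.Series
    asv_source: dict[str, str]
    c_sewage_hb_draw: pd.Series | None = None

    def __post_init__(self) -> None:
        if ((self.f < 0) | (self.f >= 1)).any():
            raise ValueError("f must lie in [0, 1) for every sample")
        bad = set(self.asv_source.values()) - set(TRUE_CATEGORY)
        if bad:
            raise ValueError(f"unknown source labels: {bad}")

    def true_categories(self) -> pd.Series:
        """Per-ASV expected partition category."""
        return pd.Series({a: TRUE_CATEGORY[s] for a, s in self.asv_source.items()})

    def to_json(self) -> str:
        return json.dumps({
            "f": self.f.to_dict(),
            "r_true": self.r_true.to_dict(),
            "hb_true": self.hb_true.to_dict(),
            "asv_source": self.asv_source,
        }, indent=2)


def _random_sequences(rng: np.random.Generator, n: int, length: int,
                      forbidden: set[str]) -> list[str]:
    """n distinct random DNA strings, disjoint from ``forbidden``."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen = set(forbidden)
    while len(out) < n:
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        if seq not in seen:  # collisions are ~4^-370 but guard anyway
            seen.add(seq)
            out.append(seq)
    return out


def generate_reference_databases(config: SyntheticConfig):
    """Generate the freshwater, sewer and human-stool reference databases.

    Sequences are random DNA of ``amplicon_length``; the three databases are
    pairwise disjoint at the full-sequence level.  Sewer and stool references
    carry a simulated 95th-percentile relative abundance in raw sewage, drawn
    log-uniformly over ``config.sewage_p95_range`` (recorded in each
    database's metadata).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    counts = {
        "freshwater": config.n_freshwater_refs,
        "sewer": config.n_sewer_refs,
        "human_stool": config.n_stool_refs,
    }
    seen: set[str] = set()
    dbs = {}
    lo, hi = config.sewage_p95_range
    for source, n in counts.items():
        seqs = _random_sequences(rng, n, config.amplicon_length, seen)
        seen.update(seqs)
        records = []
        for i, seq in enumerate(seqs):
            p95 = None
            if source != "freshwater":
                p95 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            records.append(SourceRecord(f"{source}_{i:04d}", seq, source, p95))
        meta = {"sewage_p95_distribution": "log-uniform",
                "sewage_p95_range": [lo, hi]} if source != "freshwater" else {}
        dbs[source] = SourceDatabase(records, source=source, metadata=meta)
    return dbs["freshwater"], dbs["sewer"], dbs["human_stool"]


def _draw_f(rng: np.random.Generator, config: SyntheticConfig, n: int) -> np.ndarray:
    spec = config.sewage_fraction_spec
    if spec is None:
        return np.zeros(n)
    f = spec.sample(rng, n)
    if config.truncate_f is not None:
        for _ in range(1000):
            bad = f >= config.truncate_f
            if not bad.any():
                break
            f[bad] = spec.sample(rng, int(bad.sum()))
        else:
            raise RuntimeError("sewage_fraction_spec mass above truncation point")
    return f


def generate_river_samples(config: SyntheticConfig, dbs):
    """Simulate the survey's ASV count table, sample metadata, and ground truth.

    Each sample's composition is ``(1 - r) x background + r x sewage`` where
    the background profile spans freshwater references plus unlabeled
    terrestrial ASVs, the sewage profile spans sewer plus stool references,
    and ``r`` is the composition-form read fraction implied by the sample's
    drawn ``f`` and cell concentrations.  Reads are multinomial at
    ``depth_per_sample`` (optionally Dirichlet-overdispersed).
    """
    freshwater_db, sewer_db, stool_db = dbs
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    # ASV universe: one ASV per reference plus the terrestrial pool
    asv_seqs: list[str] = []
    asv_source: list[str] = []
    for db, label in ((freshwater_db, "freshwater"), (sewer_db, "sewer"),
                      (stool_db, "human_stool")):
        for rec in db:
            asv_seqs.append(rec.sequence)
            asv_source.append(label)
    known = set(asv_seqs)
    for seq in _random_sequences(rng, config.n_terrestrial_asvs,
                                 config.amplicon_length, known):
        asv_seqs.append(seq)
        asv_source.append("terrestrial")
    asv_ids = [f"asv_{i:05d}" for i in range(len(asv_seqs))]
    source_map = dict(zip(asv_ids, asv_source))

    is_background = np.array([s in ("freshwater", "terrestrial") for s in asv_source])
    is_sewage = ~is_background
    if not is_background.any():
        raise ValueError("background pool is empty (no freshwater/terrestrial ASVs)")
    if not is_sewage.any() and config.sewage_fraction_spec is not None:
        raise ValueError("sewage pool is empty but sewage fraction is positive")

    background_profile = np.zeros(len(asv_ids))
    background_profile[is_background] = rng.dirichlet(
        np.full(int(is_background.sum()), 0.5))
    sewage_profile = np.zeros(len(asv_ids))
    if is_sewage.any():
        sewage_profile[is_sewage] = rng.dirichlet(np.full(int(is_sewage.sum()), 0.5))

    n = config.n_samples
    f = _draw_f(rng, config, n)
    c_sc = config.c_sewage_cells.sample(rng, n)
    c_rc = config.c_river_cells.sample(rng, n)
    c_sh = config.c_sewage_hb.sample(rng, n)
    r = np.asarray(sewage_read_fraction(f, c_sc, c_rc, "composition"))
    if not is_sewage.any():
        r = np.zeros_like(r)

    sites = [f"site_{i + 1:02d}" for i in range(config.n_sites)]
    n_urban = int(round(config.urban_fraction * config.n_sites))
    site_land = {s: ("urban" if i < n_urban else "rural") for i, s in enumerate(sites)}
    site_order = {s: int(rng.integers(1, 5)) for s in sites}
    site_dev = {
        s: float(rng.uniform(24, 100)) if site_land[s] == "urban"
        else float(rng.uniform(3, 23))
        for s in sites
    }
    site_quality = {s: ("impacted" if rng.random() < 0.5 else "good") for s in sites}

    sample_ids, meta_rows, count_rows = [], [], []
    k = 0
    for site in sites:
        for d in range(config.n_dates):
            sid = f"{site}_d{d + 1}"
            sample_ids.append(sid)
            meta_rows.append({
                "sample_id": sid, "site": site, "date": f"d{d + 1}",
                "land_use": site_land[site], "quality": site_quality[site],
                "stream_order": site_order[site],
                "pct_developed": round(site_dev[site], 1),
            })
            p = (1.0 - r[k]) * background_profile + r[k] * sewage_profile
            p = p / p.sum()
            if config.dirichlet_overdispersion is not None:
                positive = p > 0
                q = np.zeros_like(p)
                q[positive] = rng.dirichlet(p[positive] * config.dirichlet_overdispersion)
                p = q
            count_rows.append(rng.multinomial(config.depth_per_sample, p))
            k += 1

    counts = pd.DataFrame(count_rows, index=sample_ids, columns=asv_ids)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    table = ASVTable(counts=counts, sequences=dict(zip(asv_ids, asv_seqs)))
    truth = GroundTruth(
        f=pd.Series(f, index=sample_ids, name="f"),
        r_true=pd.Series(r, index=sample_ids, name="r_true"),
        hb_true=pd.Series(f * c_sh, index=sample_ids, name="hb_true"),
        asv_source=source_map,
        c_sewage_hb_draw=pd.Series(c_sh, index=sample_ids, name="c_sewage_hb"),
    )
    return table, metadata, truth


def generate_hb_measurements(truth: GroundTruth, config: SyntheticConfig,
                             curve: StandardCurve = DEFAULT_SYNTHETIC_CURVE) -> pd.DataFrame:
    """Censored qPCR observations coupled to the per-sample sewage fraction.

    The observed concentration is ``hb_true`` times multiplicative log-normal
    noise (``hb_noise_gsd``); observations below the LOD are reported as
    non-detect (Cq = NaN), detected values below the LOQ are flagged
    ``below_loq``.  Cq values are synthesized by inverting the standard curve
    with the default 12x reaction-to-100-ml factor, so the table round-trips
    through the quantification module.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    sigma = float(np.log(config.hb_noise_gsd))
    rows = []
    for sid, true_cn in truth.hb_true.items():
        noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
        observed = float(true_cn) * noise
        if observed < config.lod_cn_100ml:
            rows.append({"sample_id": sid, "cq": np.nan, "hb_true_cn_100ml": true_cn,
                         "hb_observed_cn_100ml": np.nan, "censor": "nondetect"})
            continue
        cn_rxn = observed / 12.0  # default ConversionConstants factor
        censor = "below_loq" if observed < config.loq_cn_100ml else "quantified"
        rows.append({"sample_id": sid, "cq": curve.cq_of(cn_rxn),
                     "hb_true_cn_100ml": true_cn,
                     "hb_observed_cn_100ml": observed, "censor": censor})
    return pd.DataFrame(rows)


def generate_bundle(config: SyntheticConfig):
    """Convenience wrapper: databases, samples, metadata, truth, qPCR table."""
    dbs = generate_reference_databases(config)
    table, metadata, truth = generate_river_samples(config, dbs)
    qpcr = generate_hb_measurements(truth, config)
    return {"databases": dbs, "table": table, "metadata": metadata,
            "truth": truth, "qpcr": qpcr}


# --- I/O -------------------------------------------------------------------

def load_config(path) -> SyntheticConfig:
    """Load a SyntheticConfig from YAML; log-normal fields are
    ``{geometric_mean: ..., geometric_sd: ...}`` mappings."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("sewage_fraction_spec", "c_sewage_hb", "c_sewage_cells",
                "c_river_cells"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = LogNormalSpec(**raw[key])
    if "sewage_p95_range" in raw:
        raw["sewage_p95_range"] = tuple(raw["sewage_p95_range"])
    return SyntheticConfig(**raw)


def write_bundle(bundle: dict, out_dir, config: SyntheticConfig | None = None) -> None:
    """Write a bundle as TSV/FASTA/CSV/JSON (plus the YAML config if given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table: ASVTable = bundle["table"]
    table.counts.to_csv(out / "counts.tsv", sep="\t")
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seq_write
    from Bio.SeqRecord import SeqRecord
    seq_write([SeqRecord(Seq(s), id=a, description="") for a, s in
               table.sequences.items()], str(out / "asvs.fasta"), "fasta")
    fw, sw, st = bundle["databases"]
    write_source_fasta(fw, out / "freshwater.fasta")
    write_source_fasta(sw, out / "sewer.fasta")
    write_source_fasta(st, out / "stool.fasta")
    bundle["metadata"].to_csv(out / "metadata.tsv", sep="\t")
    bundle["qpcr"].to_csv(out / "qpcr.csv", index=False)
    (out / "ground_truth.json").write_text(bundle["truth"].to_json())
    if config is not None:
        cfg = dataclasses.asdict(config)
        for key, val in cfg.items():
            if isinstance(val, LogNormalSpec):
                cfg[key] = {"geometric_mean": val.geometric_mean,
                            "geometric_sd": val.geometric_sd}
            elif isinstance(val, tuple):
                cfg[key] = list(val)
        (out / "config.yaml").write_text(yaml.safe_dump(cfg))
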