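"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate a bimonthly, multi-year harvest design of a single
plant species: log-normal positive LC-HRMS peak areas with multiplicative
noise and a subset of features carrying a season-specific mean shift on the
log scale; blank-only background features; 1D NMR spectra as sums of
Lorentzian peaks in the aliphatic / sugar-organic-acid / aromatic regions on
a drifting polynomial baseline with additive noise; season-conditional
climate covariates with Cerrado-like contrasts.  Every generator is
deterministic given its seed and returns ground-truth labels of the planted
discriminant variables so downstream stages have a known correct answer.

Two aspects of the planted structure mirror the reference seasonal studies
of tannin- and saponin-rich extracts rather than being uniform-random:

* discriminant metabolites belong to two opposing compound families — a
  majority family peaking in one anchor season and a minority family peaking
  in the opposite season (phenolics maxing in the dry winter, triterpenes in
  the wet summer, for instance) — so planted season assignments concentrate
  on the two anchor seasons instead of spreading evenly;
* discriminant variables sit among the more abundant signals (selection by
  variable importance operates on variance-weighted data, and seasonal
  markers reported for such extracts are major constituents), so planted
  features draw their baseline intensity from the upper end of the
  log-normal abundance distribution.

Planted NMR peaks are kept resolved (minimum center separation) and centered
inside their bucket so that the ground-truth bin labels are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ms_features import FeatureMatrix
from .nmr import Spectrum

SEASONS = ("summer", "autumn", "winter", "spring")

#: Default anchor seasons of the two planted compound families
#: (majority family first); opposite seasons of the harvest cycle.
DEFAULT_ANCHORS = ("winter", "summer")
#: Fraction of planted variables belonging to the majority family.
DEFAULT_MAJOR_FRACTION = 2.0 / 3.0

#: 1H chemical-shift regions (ppm) where synthetic peaks are placed:
#: aliphatic, sugar and organic acids, aromatic.
NMR_REGIONS = ((0.5, 2.0), (3.0, 6.0), (6.0, 9.0))

#: Season-conditional climate means and SDs, Cerrado-like: a hot rainy
#: summer, a long dry cool winter.  (mean, sd) per variable.
CLIMATE_PROFILES = {
    #            temperature   humidity      radiation      rainfall
    "summer": ((26.0, 1.5), (75.0, 5.0), (1400.0, 120.0), (250.0, 60.0)),
    "autumn": ((23.0, 1.5), (65.0, 5.0), (1100.0, 120.0), (80.0, 30.0)),
    "winter": ((19.0, 1.5), (45.0, 5.0), (900.0, 120.0), (10.0, 8.0)),
    "spring": ((25.0, 1.5), (60.0, 5.0), (1300.0, 120.0), (120.0, 40.0)),
}

#: Within-season biological + technical log-scale SD of MS peak areas (~30% CV).
DEFAULT_MS_LOG_SD = 0.3
#: Log-scale SD of NMR peak amplitudes across replicates (~25% CV).
DEFAULT_NMR_LOG_SD = 0.25


@dataclass
class GroundTruth:
    """Which synthetic variables truly differ between seasons.

    ``planted_ms`` maps feature_id -> (peak season, effect size d);
    ``blank_ms`` lists background-only feature ids; ``planted_nmr_peaks``
    maps the ppm of a planted peak center -> (peak season, effect size d).
    Planted and blank sets are disjoint by construction.
    """

    planted_ms: dict[str, tuple[str, float]] = field(default_factory=dict)
    blank_ms: list[str] = field(default_factory=list)
    planted_nmr_peaks: dict[float, tuple[str, float]] = field(default_factory=dict)

    def planted_bin_labels(self, ppm_min: float = 0.0,
                           width: float = 0.04) -> dict[str, tuple[str, float]]:
        """Labels of the buckets containing the planted NMR peak centers,
        matching :func:`seasonfuse.nmr.bin_matrix` column labels."""
        out = {}
        for center, tag in self.planted_nmr_peaks.items():
            idx = int(np.floor((center - ppm_min) / width))
            out[f"{ppm_min + width * (idx + 0.5):.3f}"] = tag
        return out


def _assign_families(n_planted: int, anchors: tuple[str, str],
                     major_fraction: float) -> list[str]:
    """Peak season per planted variable: majority family first."""
    n_major = int(np.ceil(major_fraction * n_planted))
    return [anchors[0]] * n_major + [anchors[1]] * (n_planted - n_major)


def generate_design(n_per_season: int, n_years: int, seed: int = 0,
                    species: str = "Synthetica exempli") -> pd.DataFrame:
    """Harvest design: n_per_season replicates x 4 seasons x n_years years.

    Deterministic (the seed is accepted for interface symmetry).  Columns:
    sample_id, species, season, year, replicate.
    """
    if n_per_season < 1 or n_years < 1:
        raise ValueError("n_per_season and n_years must be >= 1")
    rows = []
    for year in range(1, n_years + 1):
        for season in SEASONS:
            for rep in range(1, n_per_season + 1):
                sid = f"Y{year}_{season[:3].upper()}_R{rep}"
                rows.append((sid, species, season, year, rep))
    return pd.DataFrame(rows, columns=["sample_id", "species", "season",
                                       "year", "replicate"])


def generate_climate(design: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Season-conditional Gaussian climate covariates per sample.

    Humidity is clipped to [0, 100]; radiation and rainfall to >= 0.  By
    construction of the profiles, mean summer temperature exceeds mean winter
    temperature and winter rainfall is below spring rainfall.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in design.itertuples(index=False):
        prof = CLIMATE_PROFILES[rec.season]
        temp, hum, rad, rain = (rng.normal(m, s) for m, s in prof)
        rows.append((rec.sample_id, temp, float(np.clip(hum, 0, 100)),
                     max(rad, 0.0), max(rain, 0.0)))
    return pd.DataFrame(rows, columns=["sample_id", "temperature", "humidity",
                                       "radiation", "rainfall"])


def generate_ms_features(
    design: pd.DataFrame,
    n_features: int = 200,
    n_planted: int = 10,
    n_blank: int = 10,
    effect_size: float = 3.0,
    seed: int = 0,
    polarity: str = "positive",
    log_sd: float = DEFAULT_MS_LOG_SD,
    anchors: tuple[str, str] = DEFAULT_ANCHORS,
    major_fraction: float = DEFAULT_MAJOR_FRACTION,
) -> tuple[FeatureMatrix, GroundTruth]:
    """Aligned LC-HRMS feature table with planted seasonal effects.

    Peak areas are log-normal with a per-feature log-mean and shared log-SD.
    Baseline log-intensities are normal around 1e5 with ~1.4 log-unit spread;
    planted features draw from the abundant upper decade (1e6-1e7).  Each
    planted feature gains an additive shift of effect_size * log_sd on the
    log scale in exactly one season — its compound family's anchor season.
    Biological features carry at most a trace blank signal (sample/blank mean
    ratio >= 15 by construction); blank features are at full intensity only
    in the blank (ratio <= 0.6), so the downstream ratio filter has a
    deterministic correct answer.  m/z in [150, 2000], retention time in
    [0, 45] min.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be nonnegative")
    if n_planted + n_blank > n_features:
        raise ValueError("n_planted + n_blank must not exceed n_features")
    for season in anchors:
        if season not in SEASONS:
            raise ValueError(f"unknown anchor season {season!r}")
    rng = np.random.default_rng(seed)
    samples = design["sample_id"].tolist()
    seasons = design["season"].to_numpy()
    n_samples = len(samples)

    feature_ids = [f"F{j + 1:04d}" for j in range(n_features)]
    mz = rng.uniform(150.0, 2000.0, n_features)
    rt = rng.uniform(0.0, 45.0, n_features)

    chosen = rng.choice(n_features, size=n_planted + n_blank, replace=False)
    planted_idx = chosen[:n_planted]
    blank_idx = chosen[n_planted:]
    families = _assign_families(n_planted, anchors, major_fraction)
    planted_season = {int(j): families[k] for k, j in enumerate(planted_idx)}
    blank_set = set(int(j) for j in blank_idx)

    log_mean = rng.normal(np.log(1e5), 1.4, n_features)
    for j in planted_season:
        log_mean[j] = rng.uniform(np.log(2e6), np.log(1e7))

    areas = np.empty((n_features, n_samples))
    blank_col = np.empty(n_features)
    for j in range(n_features):
        noise = rng.normal(0.0, log_sd, n_samples)
        shift = np.zeros(n_samples)
        if j in planted_season:
            shift[seasons == planted_season[j]] = effect_size * log_sd
        vals = np.exp(log_mean[j] + shift + noise)
        if j in blank_set:
            # Background feature: full intensity in the blank only.
            blank_col[j] = float(np.exp(log_mean[j] + rng.normal(0.0, log_sd)))
            areas[j] = blank_col[j] * rng.uniform(0.05, 0.6, n_samples)
        else:
            areas[j] = vals
            # Trace carry-over into the blank, bounded so the sample/blank
            # mean ratio is provably above the default filter threshold.
            blank_col[j] = vals.mean() / rng.uniform(15.0, 100.0)

    table = pd.DataFrame({"feature_id": feature_ids, "mz": mz, "rt_min": rt,
                          "polarity": polarity})
    for i, sid in enumerate(samples):
        table[sid] = areas[:, i]
    table["blank"] = blank_col
    truth = GroundTruth(
        planted_ms={feature_ids[j]: (planted_season[j], effect_size)
                    for j in planted_season},
        blank_ms=[feature_ids[j] for j in sorted(blank_set)],
    )
    return FeatureMatrix(table, samples), truth


def _draw_peak_centers(rng: np.random.Generator, n_peaks: int,
                       regions: list[tuple[float, float]],
                       min_separation: float) -> np.ndarray:
    """Peak centers cycled over the shift regions, kept resolved.

    Each region is divided into slots of width ``min_separation``; peaks
    occupy distinct slots with a small jitter, which guarantees resolved
    resonances without rejection sampling.
    """
    n_regions = len(regions)
    jitter = 0.1 * min_separation
    centers = np.empty(n_peaks)
    for r, (lo, hi) in enumerate(regions):
        members = [k for k in range(n_peaks) if k % n_regions == r]
        n_slots = int((hi - lo) // min_separation)
        if len(members) > n_slots:
            raise ValueError(f"region ({lo}, {hi}) fits {n_slots} resolved "
                             f"peaks, needs {len(members)}")
        slots = rng.choice(n_slots, size=len(members), replace=False)
        centers[members] = (lo + (slots + 0.5) * min_separation
                            + rng.uniform(-jitter, jitter, len(members)))
    return centers


def generate_nmr_spectra(
    design: pd.DataFrame,
    n_points: int = 4096,
    ppm_range: tuple[float, float] = (0.0, 10.0),
    n_peaks: int = 30,
    n_planted: int = 5,
    effect_size: float = 3.0,
    seed: int = 0,
    log_sd: float = DEFAULT_NMR_LOG_SD,
    peak_hwhm: float = 0.006,
    bin_width_hint: float = 0.04,
    baseline_amplitude: float = 0.05,
    noise_sd: float = 0.003,
    anchors: tuple[str, str] = DEFAULT_ANCHORS,
    major_fraction: float = DEFAULT_MAJOR_FRACTION,
) -> tuple[list[Spectrum], GroundTruth]:
    """1D spectra as Lorentzian peak sums on a drifting baseline plus noise.

    Peak centers fall inside the aliphatic, sugar/organic-acid and aromatic
    regions, separated by at least three bucket widths so each resonance is
    resolved.  Peak 0 is a dominant, nearly constant reference resonance
    anchoring largest-peak normalization; planted peaks (assigned to the two
    family anchor seasons) are prominent resonances whose amplitude scales by
    exp(effect_size * log_sd) in their season, and are centered inside the
    middle of their bucket so the ground-truth bin is unambiguous.  The
    baseline is a random low-order polynomial per sample; noise is additive
    Gaussian.
    """
    lo, hi = ppm_range
    if not (0.0 <= lo < hi <= 13.0):
        raise ValueError("ppm_range must be an increasing interval within [0, 13]")
    if n_planted > n_peaks - 1:
        raise ValueError("n_planted must leave room for the reference peak")
    rng = np.random.default_rng(seed)
    ppm = np.linspace(lo, hi, n_points)

    regions = [(max(a, lo), min(b, hi)) for a, b in NMR_REGIONS]
    regions = [r for r in regions if r[1] > r[0]]
    if not regions:
        regions = [(lo, hi)]
    centers = _draw_peak_centers(rng, n_peaks, regions, 3 * bin_width_hint)
    # Reference resonance far above every other peak even after seasonal
    # elevation, so largest-peak normalization always divides by it.
    ref_amp = 3.0
    base_amp = np.concatenate([[ref_amp],
                               np.exp(rng.uniform(np.log(0.02), np.log(0.3),
                                                  n_peaks - 1))])
    amp_log_sd = np.full(n_peaks, log_sd)
    amp_log_sd[0] = 0.02  # reference peak is nearly constant

    planted = rng.choice(np.arange(1, n_peaks), size=n_planted, replace=False)
    families = _assign_families(n_planted, anchors, major_fraction)
    planted_season = {int(j): families[k] for k, j in enumerate(planted)}
    for j in planted_season:
        base_amp[j] = np.exp(rng.uniform(np.log(0.35), np.log(0.7)))
        # Snap to the middle half of the containing bucket.
        idx = np.floor((centers[j] - lo) / bin_width_hint)
        centers[j] = lo + bin_width_hint * (idx + rng.uniform(0.3, 0.7))

    spectra = []
    for rec in design.itertuples(index=False):
        intensity = np.zeros(n_points)
        for k in range(n_peaks):
            shift = (effect_size * log_sd
                     if planted_season.get(k) == rec.season else 0.0)
            amp = base_amp[k] * np.exp(shift + rng.normal(0.0, amp_log_sd[k]))
            intensity += amp * peak_hwhm ** 2 / ((ppm - centers[k]) ** 2
                                                 + peak_hwhm ** 2)
        coeffs = rng.normal(0.0, baseline_amplitude, 3)
        x = (ppm - lo) / (hi - lo)
        intensity += coeffs[0] + coeffs[1] * x + coeffs[2] * x ** 2
        intensity += rng.normal(0.0, noise_sd, n_points)
        spectra.append(Spectrum(ppm, intensity, sample_id=rec.sample_id))

    truth = GroundTruth(planted_nmr_peaks={
        float(centers[j]): (planted_season[j], effect_size)
        for j in planted_season})
    return spectra, truth


# ---------------------------------------------------------------------------
# Toy compound reference library

_LIBRARY_RECORDS = [
    # B-type proanthocyanidins (flavan-3-ol oligomers, C-C interflavan bonds)
    ("catechin (flavan-3-ol monomer)", "C15H14O6", "proanthocyanidin"),
    ("procyanidin B-type dimer", "C30H26O12", "proanthocyanidin"),
    ("procyanidin B-type trimer", "C45H38O18", "proanthocyanidin"),
    ("procyanidin B-type tetramer", "C60H50O24", "proanthocyanidin"),
    # A-type proanthocyanidins (one extra ether linkage, two H fewer each)
    ("procyanidin A-type dimer", "C30H24O12", "proanthocyanidin"),
    ("procyanidin A-type trimer", "C45H36O18", "proanthocyanidin"),
    ("procyanidin A-type tetramer", "C60H48O24", "proanthocyanidin"),
    ("procyanidin A-type pentamer", "C75H60O30", "proanthocyanidin"),
    # Galloylquinic acid series (quinic acid + n galloyl residues)
    ("mono-O-galloylquinic acid", "C14H16O10", "galloylquinic acid"),
    ("di-O-galloylquinic acid", "C21H20O14", "galloylquinic acid"),
    ("tri-O-galloylquinic acid", "C28H24O18", "galloylquinic acid"),
    ("tetra-O-galloylquinic acid", "C35H28O22", "galloylquinic acid"),
    # Galloylshikimic acid series
    ("mono-O-galloylshikimic acid", "C14H14O9", "galloylshikimic acid"),
    ("di-O-galloylshikimic acid", "C21H18O13", "galloylshikimic acid"),
    ("tri-O-galloylshikimic acid", "C28H22O17", "galloylshikimic acid"),
    # Pentacyclic triterpene acids and relatives (lupane/oleanane skeletons)
    ("betulinic acid", "C30H48O3", "triterpene"),
    ("oleanolic acid", "C30H48O3", "triterpene"),
    ("beta-amyrin", "C30H50O", "triterpene"),
    ("3-oxo-olean-12-en-28-al", "C30H46O2", "triterpene"),
    ("hydroxy-oleanenedioic acid type", "C30H46O5", "triterpene"),
    ("trihydroxy-oleanenoic acid type", "C30H48O5", "triterpene"),
    # Glycosylated flavonoids
    ("quercetin-O-hexoside", "C21H20O12", "glycosylated flavonoid"),
    ("quercetin-O-deoxyhexoside", "C21H20O11", "glycosylated flavonoid"),
    ("quercetin-O-pentoside", "C20H18O11", "glycosylated flavonoid"),
    ("rutin (quercetin-O-rutinoside)", "C27H30O16", "glycosylated flavonoid"),
    ("quercetin-O-(O-galloyl)-hexoside", "C28H24O16", "glycosylated flavonoid"),
    ("vitexin (apigenin-C-hexoside)", "C21H20O10", "glycosylated flavonoid"),
    ("luteolin-C-hexoside", "C21H20O11", "glycosylated flavonoid"),
    # Flavonoid aglycones
    ("quercetin", "C15H10O7", "flavonoid aglycone"),
    ("kaempferol", "C15H10O6", "flavonoid aglycone"),
    ("apigenin", "C15H10O5", "flavonoid aglycone"),
    # Cinnamic acids and conjugates
    ("caffeic acid", "C9H8O4", "cinnamic acid"),
    ("p-coumaric acid", "C9H8O3", "cinnamic acid"),
    ("ferulic acid", "C10H10O4", "cinnamic acid"),
    ("chlorogenic acid (caffeoylquinic)", "C16H18O9", "cinnamic acid"),
    # Phenolic and core organic acids
    ("gallic acid", "C7H6O5", "phenolic acid"),
    ("protocatechuic acid", "C7H6O4", "phenolic acid"),
    ("quinic acid", "C7H12O6", "organic acid"),
    ("shikimic acid", "C7H10O5", "organic acid"),
    # Triterpenic saponins (oleanane aglycone + sugar chains)
    ("oleanolic acid triglycoside saponin", "C48H78O18", "saponin"),
    ("hederagenin tetraglycoside saponin", "C53H86O22", "saponin"),
    ("oleanane bisdesmosidic saponin", "C54H88O23", "saponin"),
]


def generate_reference_library(seed: int = 0) -> pd.DataFrame:
    """Toy stand-in for a natural-products dereplication database.

    A fixed, curated table (the seed is accepted for interface symmetry) of
    >= 30 CHNO natural products spanning the compound classes relevant to
    tannin- and saponin-rich plant extracts, with formulas whose protonated /
    deprotonated masses match the worked-example ions within 5 ppm.
    """
    return pd.DataFrame(_LIBRARY_RECORDS, columns=["name", "formula", "class"])


# ---------------------------------------------------------------------------
# Plain-CSV writers for the generated inputs

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth table (never read by the pipeline itself)."""
    rows = [("ms_feature", fid, season, d)
            for fid, (season, d) in truth.planted_ms.items()]
    rows += [("blank_feature", fid, "", np.nan) for fid in truth.blank_ms]
    rows += [("nmr_peak", f"{c:.4f}", season, d)
             for c, (season, d) in truth.planted_nmr_peaks.items()]
    pd.DataFrame(rows, columns=["kind", "id", "season", "effect_size"]).to_csv(
        path, index=False)
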