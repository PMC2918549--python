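"""Ground-truth generator for GeLC-MS/MS-like PSM tables.

Emulates the experimental design the pipeline targets: six brain
regions x replicate animals x 24 gel slices.  Proteins are separated
into slices by molecular weight (heaviest protein -> slice 1, 24
equal-quantile bins), digested with up to one missed cleavage, and
detectable peptides are sampled per replicate.  Detected PSMs carry
Mascot-like ion scores guaranteed above a fixed significance threshold;
noise PSMs are sub-threshold or carry <= 3 matched ions.  Shared
peptides between designated homolog pairs exercise the parsimony
assignment.  All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from regioprot.errors import ValidationError
from regioprot.io_formats import ProteinEntry, PsmRecord
from regioprot.localization import CATEGORIES
from regioprot.mass_fragments import (
    MOD_DELTAS,
    PARENT_TOLERANCE_DA,
    PROTON_MASS,
    digest,
    peptide_mass,
)
from regioprot.region_compare import DEFAULT_REGIONS

# empirical compartment frequencies used for synthetic annotations
COMPARTMENT_FREQUENCIES = {
    "membrane": 0.200,
    "cytoplasm": 0.195,
    "mitochondrion": 0.171,
    "cytoskeleton": 0.082,
    "nucleus": 0.047,
    "extracellular region": 0.033,
    "other": 0.180,
    "ND": 0.092,
}

_AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # K/R handled separately


@dataclass
class SyntheticDesign:
    """Parameters of one simulated experiment."""

    n_proteins: int = 200
    regions: tuple[str, ...] = tuple(DEFAULT_REGIONS)
    n_replicates: int = 3
    n_slices: int = 24
    unique_fraction: float = 0.10  # per-region fraction planted unique
    profiles: dict[str, tuple] | None = None  # accession -> profile
    threshold_score: float = 40.0
    score_shape: float = 2.0
    score_scale: float = 15.0
    detect_prob: float = 0.6  # per candidate peptide per replicate
    good_ion_prob: float = 0.95  # P[(b+y) > 3] for true PSMs
    mod_prob: float = 0.1
    noise_rate: float = 0.3  # noise PSMs per true PSM
    noise_low_ion_frac: float = 0.3  # noise with score > threshold, ions <= 3
    shared_peptide_rate: float = 0.0
    n_homolog_pairs: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "unique_fraction",
            "detect_prob",
            "good_ion_prob",
            "mod_prob",
            "noise_low_ion_frac",
            "shared_peptide_rate",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if len(self.regions) < 1:
            raise ValidationError("at least one region required")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        if self.noise_rate < 0:
            raise ValidationError("noise_rate must be >= 0")
        if self.threshold_score < 0:
            raise ValidationError("threshold_score must be >= 0")
        n_unique_total = int(
            round(self.unique_fraction * self.n_proteins)
        ) * len(self.regions)
        if n_unique_total > self.n_proteins:
            raise ValidationError(
                "unique_fraction too large for n_proteins"
            )


@dataclass
class SyntheticTruth:
    """Planted design plus per-PSM provenance for recovery tests."""

    design: SyntheticDesign
    planted_unique: dict[str, set[str]]  # region -> accessions
    true_detected: dict[str, set[str]]  # region -> accessions
    true_unique: dict[str, set[str]]  # planted & actually detectable
    provenance: dict[str, str] = field(default_factory=dict)  # spectrum id


def generate_proteome(
    n: int,
    length_range: tuple[int, int] = (150, 600),
    seed: int = 0,
) -> list[ProteinEntry]:
    """Random protein entries with ~10% K+R so tryptic peptides average
    8-15 residues.  Deterministic given the seed."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if length_range[0] < 30:
        raise ValidationError("minimum protein length is 30")
    rng = np.random.default_rng(seed)
    # K+R at 10% total; remaining mass spread over the other 18 residues
    residues = list(_AMINO_ACIDS) + ["K", "R"]
    probs = [0.9 / 18] * 18 + [0.055, 0.045]
    entries = []
    width = len(str(n))
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        entries.append(
            ProteinEntry(
                accession=f"SYNP{i + 1:0{width}d}", sequence=seq
            )
        )
    return entries


def _assign_profiles(
    proteome: Sequence[ProteinEntry], design: SyntheticDesign
) -> dict[str, tuple]:
    """Default planting: the first k proteins per region are unique to
    that region (round-robin), the rest ubiquitous."""
    if design.profiles is not None:
        return dict(design.profiles)
    per_region = int(round(design.unique_fraction * design.n_proteins))
    profiles: dict[str, tuple] = {}
    idx = 0
    for region in design.regions:
        for _ in range(per_region):
            profiles[proteome[idx].accession] = ("region_unique", region)
            idx += 1
    for entry in proteome[idx:]:
        profiles[entry.accession] = ("ubiquitous",)
    return profiles


def _profile_weight(profile: tuple, region: str) -> float:
    kind = profile[0]
    if kind == "ubiquitous":
        return 1.0
    if kind == "region_unique":
        return 1.0 if profile[1] == region else 0.0
    if kind == "graded":
        return float(profile[1].get(region, 0.0))
    raise ValidationError(f"unknown profile kind {kind!r}")


def _slice_bins(
    proteome: Sequence[ProteinEntry], n_slices: int
) -> dict[str, int]:
    """Equal-quantile molecular-weight bins; heaviest protein -> slice 1."""
    masses = {
        entry.accession: peptide_mass(entry.sequence)
        for entry in proteome
    }
    ordered = sorted(masses, key=lambda acc: -masses[acc])
    n = len(ordered)
    return {
        acc: min(n_slices, i * n_slices // n + 1)
        for i, acc in enumerate(ordered)
    }


def _candidate_peptides(sequence: str) -> list[str]:
    """Detectable tryptic peptides: 6-25 residues, <= 1 missed cleavage."""
    return [
        p.sequence
        for p in digest(sequence, max_missed=1)
        if 6 <= len(p.sequence) <= 25
    ]


def _draw_ion_counts(
    rng: np.random.Generator, peptide_len: int, good: bool
) -> tuple[int, int]:
    max_ions = peptide_len - 1
    if good:
        n_b = int(rng.integers(2, max(3, max_ions + 1)))
        n_y = int(rng.integers(2, max(3, max_ions + 1)))
        return n_b, n_y
    n_b = int(rng.integers(0, 2))
    n_y = int(rng.integers(0, 4 - n_b))
    return n_b, n_y


def _draw_modifications(
    rng: np.random.Generator, sequence: str, mod_prob: float
) -> tuple[tuple[int, str], ...]:
    if rng.random() >= mod_prob:
        return ()
    met = [i + 1 for i, res in enumerate(sequence) if res == "M"]
    cys = [i + 1 for i, res in enumerate(sequence) if res == "C"]
    options: list[tuple[int, str]] = []
    options.extend((pos, "Oxidation") for pos in met)
    options.extend((pos, "Carbamidomethyl") for pos in cys)
    options.extend((pos, "Propionamide") for pos in cys)
    if not options:
        return ()
    return (options[int(rng.integers(0, len(options)))],)


def simulate_psms(
    proteome: Sequence[ProteinEntry], design: SyntheticDesign
) -> tuple[dict[tuple[str, str], list[PsmRecord]], SyntheticTruth]:
    """Emit per-(region, replicate) PSM tables plus ground truth.

    ``true_detected[region]`` holds proteins that produced at least one
    retainable true PSM (score above threshold and > 3 matched ions) in
    that region, so a zero-noise, no-sharing design is recovered exactly
    by the inference pipeline.
    """
    design.validate()
    if len(proteome) != design.n_proteins:
        raise ValidationError(
            f"proteome has {len(proteome)} entries but design declares "
            f"{design.n_proteins}"
        )
    rng = np.random.default_rng(design.seed)
    profiles = _assign_profiles(proteome, design)
    slices = _slice_bins(proteome, design.n_slices)
    peptides_by_protein = {
        entry.accession: _candidate_peptides(entry.sequence)
        for entry in proteome
    }
    homolog_partner: dict[str, str] = {}
    if design.n_homolog_pairs > 0:
        ubiquitous = [
            entry.accession
            for entry in proteome
            if profiles[entry.accession][0] == "ubiquitous"
        ]
        if len(ubiquitous) < 2 * design.n_homolog_pairs:
            raise ValidationError(
                "not enough ubiquitous proteins for homolog pairs"
            )
        for i in range(design.n_homolog_pairs):
            a, b = ubiquitous[2 * i], ubiquitous[2 * i + 1]
            homolog_partner[a] = b
            homolog_partner[b] = a

    replicate_ids = [f"rat{i + 1}" for i in range(design.n_replicates)]
    tables: dict[tuple[str, str], list[PsmRecord]] = {}
    planted_unique: dict[str, set[str]] = {
        r: set() for r in design.regions
    }
    for accession, profile in profiles.items():
        if profile[0] == "region_unique":
            planted_unique[profile[1]].add(accession)
    true_detected: dict[str, set[str]] = {r: set() for r in design.regions}
    provenance: dict[str, str] = {}
    spectrum_counter = 0

    def make_psm(
        region: str,
        replicate: str,
        accession: str,
        sequence: str,
        is_noise: bool,
    ) -> PsmRecord:
        nonlocal spectrum_counter
        spectrum_counter += 1
        spectrum_id = f"spec{spectrum_counter:07d}"
        mods = _draw_modifications(rng, sequence, design.mod_prob)
        charge = int(rng.choice([2, 3], p=[0.7, 0.3]))
        mass = peptide_mass(sequence, mods)
        jitter = float(
            rng.uniform(-PARENT_TOLERANCE_DA, PARENT_TOLERANCE_DA)
        )
        mz = (mass + jitter + charge * PROTON_MASS) / charge
        if is_noise:
            low_ions = rng.random() < design.noise_low_ion_frac
            if low_ions:
                # passes the score rule but fails the ion rule
                score = design.threshold_score + float(
                    rng.gamma(design.score_shape, design.score_scale)
                )
                n_b, n_y = _draw_ion_counts(rng, len(sequence), good=False)
            else:
                score = float(
                    rng.uniform(5.0, design.threshold_score * 0.999)
                )
                n_b, n_y = _draw_ion_counts(
                    rng, len(sequence), good=rng.random() < 0.5
                )
        else:
            score = design.threshold_score + float(
                rng.gamma(design.score_shape, design.score_scale)
            ) + 1e-6
            good = rng.random() < design.good_ion_prob
            n_b, n_y = _draw_ion_counts(rng, len(sequence), good=good)
        candidates = [accession]
        partner = homolog_partner.get(accession)
        if (
            partner is not None
            and not is_noise
            and rng.random() < design.shared_peptide_rate
        ):
            candidates.append(partner)
        record = PsmRecord(
            region=region,
            replicate_id=replicate,
            slice_index=slices[accession],
            spectrum_id=spectrum_id,
            peptide_sequence=sequence,
            modifications=mods,
            charge=charge,
            precursor_mz=mz,
            ion_score=round(score, 4),
            threshold_score=design.threshold_score,
            n_b_matched=n_b,
            n_y_matched=n_y,
            candidate_accessions=tuple(candidates),
        )
        provenance[spectrum_id] = "noise" if is_noise else "true"
        return record

    all_accessions = [entry.accession for entry in proteome]
    for region in design.regions:
        for replicate in replicate_ids:
            rows: list[PsmRecord] = []
            for entry in proteome:
                weight = _profile_weight(profiles[entry.accession], region)
                if weight <= 0.0:
                    continue
                for sequence in peptides_by_protein[entry.accession]:
                    if rng.random() >= design.detect_prob * weight:
                        continue
                    rec = make_psm(
                        region, replicate, entry.accession, sequence,
                        is_noise=False,
                    )
                    rows.append(rec)
                    if (
                        rec.ion_score > rec.threshold_score
                        and rec.n_b_matched + rec.n_y_matched > 3
                    ):
                        true_detected[region].add(entry.accession)
            n_noise = int(round(design.noise_rate * len(rows)))
            for _ in range(n_noise):
                accession = all_accessions[
                    int(rng.integers(0, len(all_accessions)))
                ]
                candidates = peptides_by_protein[accession]
                if not candidates:
                    continue
                sequence = candidates[
                    int(rng.integers(0, len(candidates)))
                ]
                rows.append(
                    make_psm(
                        region, replicate, accession, sequence,
                        is_noise=True,
                    )
                )
            tables[(region, replicate)] = rows

    true_unique = {
        region: planted_unique[region] & true_detected[region]
        for region in design.regions
    }
    truth = SyntheticTruth(
        design=design,
        planted_unique=planted_unique,
        true_detected=true_detected,
        true_unique=true_unique,
        provenance=provenance,
    )
    return tables, truth


def generate_annotations(
    accessions: Sequence[str], seed: int = 0
) -> dict[str, list[str]]:
    """Draw a primary compartment per protein from the empirical
    category frequencies; some proteins get secondary compartments."""
    rng = np.random.default_rng(seed)
    categories = list(COMPARTMENT_FREQUENCIES)
    probs = np.array([COMPARTMENT_FREQUENCIES[c] for c in categories])
    probs = probs / probs.sum()
    annotations: dict[str, list[str]] = {}
    for accession in accessions:
        primary = str(rng.choice(categories, p=probs))
        labels = [primary]
        if primary != "ND" and rng.random() < 0.25:
            secondary = str(rng.choice(categories, p=probs))
            if secondary not in labels and secondary != "ND":
                labels.append(secondary)
        annotations[accession] = labels
    return annotations


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    path = Path(path)
    payload = {
        "design": asdict(truth.design),
        "planted_unique": {
            r: sorted(s) for r, s in truth.planted_unique.items()
        },
        "true_detected": {
            r: sorted(s) for r, s in truth.true_detected.items()
        },
        "true_unique": {
            r: sorted(s) for r, s in truth.true_unique.items()
        },
        "provenance": truth.provenance,
    }
    payload["design"]["regions"] = list(truth.design.regions)
    path.write_text(
        json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8"
    )


def load_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    design_dict = payload["design"]
    design_dict["regions"] = tuple(design_dict["regions"])
    if design_dict.get("profiles") is not None:
        design_dict["profiles"] = {
            k: tuple(v) for k, v in design_dict["profiles"].items()
        }
    design = SyntheticDesign(**design_dict)
    return SyntheticTruth(
        design=design,
        planted_unique={
            r: set(v) for r, v in payload["planted_unique"].items()
        },
        true_detected={
            r: set(v) for r, v in payload["true_detected"].items()
        },
        true_unique={
            r: set(v) for r, v in payload["true_unique"].items()
        },
        provenance=payload["provenance"],
    )
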