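"""File I/O, run configuration, pipeline orchestration and simulation.

The pipeline is the paper-style two-stage search: digest the protein,
keep the cysteine-containing peptides, match approximate disulfide
precursor masses against the precursor list (Initial Matches), match
approximate fragment structure masses against each precursor's MS/MS
peaks (Validation Matches), score each candidate cysteine pair, and
report the maximum-weight matching of the resulting bond graph as the
globally consistent topology.

The simulator builds a random protein with planted disulfide bonds and
emits the corresponding precursor masses and fragment spectra (plus
decoy peaks), for closed-loop testing of the whole chain.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio import SeqIO
from pyteomics import mgf as ptmgf

from . import dms as dms_mod
from . import fms as fms_mod
from . import params as params_mod
from . import score_topology as score_mod
from .masschem import (
    PROTON,
    DisulfideStructure,
    Peptide,
    ResidueMassTable,
    default_table,
    digest,
    extract_ccp,
    structure_mass,
)

logger = logging.getLogger("sslinker")

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: V_s thresholds: multi-ion searches support a stricter cut than b/y-only.
THRESHOLD_MULTI_ION = 80.0
THRESHOLD_BY_ONLY = 30.0


@dataclass
class RunConfig:
    """Search parameters; defaults follow the published operating point."""

    enzyme: str = "trypsin"
    missed_cleavages: int = 0
    ion_types: tuple[str, ...] = fms_mod.ION_TYPES
    epsilon: float | str = "auto"
    delta: float | str = "auto"
    t_im: float = 1.0
    t_vm: float = 1.0
    score_threshold: float | None = None
    intensity_floor: float = 0.10
    k_max: int = 3
    mass_scale: str = "monoisotopic"
    seed: int = 0
    consider_charge2: bool = False
    epsilon_model: params_mod.RegressionModel | None = None
    delta_model: params_mod.RegressionModel | None = None

    def __post_init__(self):
        for name in ("t_im", "t_vm", "intensity_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.ion_types) - set(fms_mod.ION_TYPES)
        if unknown:
            raise ValueError(f"unsupported ion types: {sorted(unknown)}")
        self.ion_types = tuple(self.ion_types)
        if self.score_threshold is None:
            by_only = set(self.ion_types) <= {"b", "y"}
            self.score_threshold = THRESHOLD_BY_ONLY if by_only else THRESHOLD_MULTI_ION

    @property
    def charges(self) -> tuple[int, ...]:
        return (1, 2) if self.consider_charge2 else (1,)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "ion_types" in payload and isinstance(payload["ion_types"], str):
            payload["ion_types"] = tuple(payload["ion_types"].split(","))
        return cls(**payload)

    def resolve_epsilon(self, ccp: Sequence[Peptide], pms_value: float) -> float:
        """Literal value, regression model, or guarded default.

        The trimming step near the target mass removes elements up to a
        factor (1+eps) apart, so detection of a true precursor inside
        the +-t_im window is only guaranteed when eps * pms < t_im; the
        automatic default is therefore capped at t_im / (2 * pms).
        """
        if self.epsilon != "auto":
            return float(self.epsilon)
        if self.epsilon_model is not None and ccp:
            return params_mod.predict_epsilon(
                self.epsilon_model, params_mod.epsilon_features(ccp)
            )
        return min(params_mod.DEFAULT_EPSILON, self.t_im / (2.0 * pms_value))

    def resolve_delta(self, max_mass: float, avg_fragment_len: float = 8.0) -> float:
        if self.delta != "auto":
            return float(self.delta)
        if self.delta_model is not None:
            return params_mod.predict_delta(
                self.delta_model, params_mod.delta_features(avg_fragment_len)
            )
        return min(params_mod.DEFAULT_DELTA, self.t_vm / (2.0 * max_mass))


# ---------------------------------------------------------------------------
# File readers / writers
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """One precursor (neutral mass, possibly unknown) and its peak list."""

    precursor_mass: float | None
    peaks: list[tuple[float, float]]
    title: str = ""


def read_fasta(path, record_id: str | None = None) -> tuple[str, str]:
    """(id, sequence) of the requested record, or the first one."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if record_id is None:
        rec = records[0]
    else:
        try:
            rec = next(r for r in records if r.id == record_id)
        except StopIteration:
            raise ValueError(f"{path}: no record with id {record_id!r}")
    return rec.id, str(rec.seq).upper()


def read_pms(path) -> list[float]:
    """Neutral precursor masses from plain text/CSV (one value per line)
    or from MGF PEPMASS/CHARGE fields (neutralized as m/z*z - z*proton)."""
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        return [s.precursor_mass for s in read_peaklist(path) if s.precursor_mass]
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip().replace(",", " ")
            if not line:
                continue
            try:
                values.append(float(line.split()[0]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: not a mass value: {line!r}")
    return values


def read_peaklist(path, fmt: str | None = None) -> list[Spectrum]:
    """Spectra from MGF or two-column (m/z, intensity) CSV."""
    path = Path(path)
    fmt = fmt or ("mgf" if path.suffix.lower() == ".mgf" else "csv")
    if fmt == "mgf":
        out = []
        with ptmgf.MGF(str(path)) as reader:
            for spec in reader:
                pep = spec["params"].get("pepmass")
                charge = spec["params"].get("charge")
                mass = None
                if pep:
                    mz = pep[0] if isinstance(pep, (tuple, list)) else float(pep)
                    z = int(charge[0]) if charge else 1
                    mass = mz * z - z * PROTON
                peaks = list(zip(spec["m/z array"].tolist(), spec["intensity array"].tolist()))
                out.append(Spectrum(precursor_mass=mass, peaks=peaks,
                                    title=spec["params"].get("title", "")))
        return out
    if fmt == "csv":
        peaks = []
        with open(path) as fh:
            for lineno, row in enumerate(csv.reader(fh), 1):
                if not row or not row[0].strip():
                    continue
                try:
                    peaks.append((float(row[0]), float(row[1])))
                except (ValueError, IndexError):
                    raise ValueError(f"{path}:{lineno}: expected 'm/z,intensity' row")
        return [Spectrum(precursor_mass=None, peaks=peaks, title=path.stem)]
    raise ValueError(f"unknown peak-list format {fmt!r}")


def write_peaklist(path, spectra: Sequence[Spectrum], fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("mgf" if path.suffix.lower() == ".mgf" else "csv")
    if fmt == "mgf":
        entries = []
        for spec in spectra:
            mz = np.array([p[0] for p in spec.peaks])
            entries.append({
                "m/z array": mz,
                "intensity array": np.array([p[1] for p in spec.peaks]),
                "params": {
                    "title": spec.title,
                    "pepmass": (spec.precursor_mass or 0.0) + PROTON,
                    "charge": "1+",
                },
            })
        ptmgf.write(entries, str(path), file_mode="w")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for spec in spectra:
            for mz, intensity in spec.peaks:
                writer.writerow([f"{mz:.6f}", f"{intensity:.6f}"])


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class StageLog:
    """Search-space accounting for one precursor."""

    pms_value: float
    epsilon: float
    dms_retained: int
    dms_trimmed: int
    initial_matches: int
    fms_retained: int = 0
    fms_total: int = 0
    validation_matches: int = 0
    seconds: float = 0.0


@dataclass
class PipelineResult:
    bonds: list[score_mod.BondScore]
    topology: set[score_mod.CysPair]
    initial_matches: list[dms_mod.InitialMatch]
    logs: list[StageLog]
    cys_positions: list[int]
    config: RunConfig

    def all_cys_pairs(self) -> list[score_mod.CysPair]:
        cys = self.cys_positions
        return [(a, b) for i, a in enumerate(cys) for b in cys[i + 1:]]


def _bond_to_protein_pairs(structure: DisulfideStructure) -> list[score_mod.CysPair]:
    """1-based protein residue positions of each assigned bond."""
    pairs = []
    for (i, ci), (j, cj) in structure.bonded_pairs or ():
        p1, p2 = structure.peptides[i], structure.peptides[j]
        if p1.start < 0 or p2.start < 0:
            continue  # mass-only peptides carry no protein coordinates
        pairs.append(tuple(sorted((p1.start + ci + 1, p2.start + cj + 1))))
    return pairs


def run_search(
    protein: str | None,
    pms: Sequence[float],
    spectra: Sequence[Spectrum | None],
    config: RunConfig,
    ccp: Sequence[Peptide] | None = None,
    table: ResidueMassTable | None = None,
) -> PipelineResult:
    """Run the two-stage search on in-memory inputs.

    ``spectra`` is parallel to ``pms`` (entries may be None when only
    first-stage matching is wanted, e.g. mass-list mode).  ``ccp`` may
    be given directly to bypass digestion.
    """
    table = table or default_table()
    if ccp is None:
        if protein is None:
            raise ValueError("either a protein sequence or a CCP list is required")
        peptides = digest(protein, config.enzyme, config.missed_cleavages,
                          scale=config.mass_scale, table=table)
        ccp = extract_ccp(peptides)
    if not ccp:
        logger.warning("no cysteine-containing peptides: empty report")
    if len(spectra) not in (0, len(pms)):
        raise ValueError("spectra list must be empty or parallel to the PMS list")
    spectra = list(spectra) or [None] * len(pms)

    cys_positions = sorted(
        p.start + off + 1 for p in ccp if p.start >= 0 for off in p.cys_positions
    )
    logs: list[StageLog] = []
    all_matches: list[dms_mod.InitialMatch] = []
    evidence: dict[score_mod.CysPair, score_mod.BondScore] = {}

    for pms_value, spectrum in zip(pms, spectra):
        t0 = time.perf_counter()
        eps = config.resolve_epsilon(ccp, pms_value)
        dms, declared = dms_mod.approx_dms(ccp, pms_value, eps, config.t_im, config.k_max)
        log = StageLog(
            pms_value=pms_value,
            epsilon=eps,
            dms_retained=len(dms.entries),
            dms_trimmed=len(dms.trimmed),
            initial_matches=0,
        )
        if declared is not None:
            candidates = []
            for cand in dms_mod.window_candidates(dms, pms_value, config.t_im):
                for assigned in dms_mod.enumerate_bond_assignments(cand):
                    candidates.append(
                        dms_mod.InitialMatch(
                            structure=assigned,
                            pms_value=pms_value,
                            delta=abs(cand.mass - pms_value),
                        )
                    )
            log.initial_matches = len(candidates)
            all_matches.extend(candidates)
            if spectrum is not None and spectrum.peaks:
                _score_candidates(candidates, spectrum, config, table, evidence, log)
        log.seconds = time.perf_counter() - t0
        logger.info(
            "PMS %.2f: eps=%.2e DMS %d retained / %d trimmed, %d IM, %d VM (%.2fs)",
            pms_value, eps, log.dms_retained, log.dms_trimmed,
            log.initial_matches, log.validation_matches, log.seconds,
        )
        logs.append(log)

    bonds = sorted(evidence.values(), key=lambda b: -b.v_s)
    graph = score_mod.build_bond_graph(bonds, config.score_threshold)
    topology = score_mod.max_weight_topology(graph)
    return PipelineResult(
        bonds=bonds,
        topology=topology,
        initial_matches=all_matches,
        logs=logs,
        cys_positions=cys_positions,
        config=config,
    )


def _score_candidates(candidates, spectrum, config, table, evidence, log) -> None:
    normalized = score_mod.normalize_intensity(spectrum.peaks)
    avg_len = float(np.mean([
        len(p) for im in candidates for p in im.structure.peptides if p.sequence
    ])) if candidates else 8.0
    max_mass = max(m for m, _ in normalized) * max(config.charges)
    delta = config.resolve_delta(max_mass, avg_len / 2.0)
    for im in candidates:
        if any(p.sequence is None for p in im.structure.peptides):
            continue
        fms = fms_mod.build_fms(im.structure, delta, config.ion_types, table)
        vms = fms_mod.find_validation_matches(
            im, normalized, delta, config.t_vm, config.ion_types,
            config.intensity_floor, config.charges, table, fms=fms,
        )
        log.fms_retained = max(log.fms_retained, fms.size)
        log.fms_total = max(log.fms_total, len(fms.entries))
        log.validation_matches += len(vms)
        if not vms:
            continue
        v_s = score_mod.match_score(vms, normalized, config.intensity_floor)
        mass_range = max(f[0] for f in fms.retained) - min(f[0] for f in fms.retained)
        pp, pp2 = score_mod.pp_scores(
            vms, normalized, fms.size, config.t_vm, max(mass_range, 1.0),
            config.intensity_floor, seed=config.seed,
        )
        for pair in _bond_to_protein_pairs(im.structure):
            best = evidence.get(pair)
            if best is None or v_s > best.v_s:
                evidence[pair] = score_mod.BondScore(
                    cys_pair=pair, v_s=v_s, pp=pp, pp2=pp2,
                    vms=tuple(vms), precursor=im.pms_value,
                )


def run_pipeline(
    fasta: str | Path,
    pms_file: str | Path,
    spectra_files: Sequence[str | Path],
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """File-based front end: parse inputs, run the search, write reports."""
    _, protein = read_fasta(fasta)
    pms = read_pms(pms_file)
    if not pms:
        raise ValueError(f"{pms_file}: no precursor masses")
    spectra: list[Spectrum | None] = []
    for path in spectra_files:
        spectra.extend(read_peaklist(path))
    if spectra and len(spectra) != len(pms):
        raise ValueError(
            f"{len(spectra)} spectra for {len(pms)} precursors; counts must agree"
        )
    result = run_search(protein, pms, spectra, config)
    if out_dir is not None:
        write_reports(result, out_dir)
    return result


def write_reports(result: PipelineResult, out_dir: str | Path) -> None:
    """TSV bond table + JSON summary (scores, topology, search-space log)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "bonds.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["cys_a", "cys_b", "v_s", "pp", "pp2", "n_vm", "precursor", "in_topology"])
        for bond in result.bonds:
            writer.writerow([
                bond.cys_pair[0], bond.cys_pair[1],
                f"{bond.v_s:.2f}", f"{bond.pp:.2f}", f"{bond.pp2:.2f}",
                len(bond.vms), f"{bond.precursor:.4f}" if bond.precursor else "",
                int(bond.cys_pair in result.topology),
            ])
    with open(out / "initial_matches.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["pms_value", "peptides", "bonded_pairs", "mass", "delta"])
        for im in result.initial_matches:
            writer.writerow([
                f"{im.pms_value:.4f}",
                im.structure.name,
                ";".join(f"{a}-{b}" for a, b in _bond_to_protein_pairs(im.structure)),
                f"{im.structure.mass:.4f}",
                f"{im.delta:.4f}",
            ])
    with open(out / "validation_matches.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["precursor", "cys_a", "cys_b", "fragments",
                         "theoretical_mass", "observed_mz", "delta", "intensity"])
        for bond in result.bonds:
            for vm in bond.vms:
                best = min(vm.structures, key=lambda s: abs(s.neutral_mass - vm.neutral_mass))
                writer.writerow([
                    f"{bond.precursor:.4f}" if bond.precursor else "",
                    bond.cys_pair[0], bond.cys_pair[1],
                    best.name,
                    f"{best.neutral_mass:.4f}",
                    f"{vm.peak[0]:.4f}",
                    f"{vm.delta:.4f}",
                    f"{vm.peak[1]:.4f}",
                ])
    summary = {
        "topology": sorted(map(list, result.topology)),
        "score_threshold": result.config.score_threshold,
        "cysteines": result.cys_positions,
        "search_space": [asdict(log) for log in result.logs],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)


# ---------------------------------------------------------------------------
# Synthetic dataset simulation
# ---------------------------------------------------------------------------

#: Residues used for random peptide bodies: no C/K/R/P so cleavage sites
#: and cysteines are planted only where intended.
_BODY_RESIDUES = "ADEFGHILMNQSTVWY"


@dataclass
class SyntheticDataset:
    """A random protein with planted S-S bonds and matching spectra."""

    protein: str
    topology: set[score_mod.CysPair]
    pms: list[float]
    spectra: list[Spectrum]
    structures: list[DisulfideStructure]
    seed: int
    peptides: list[Peptide] = field(default_factory=list)


def simulate_dataset(
    protein_length: int = 60,
    n_bonds: int = 2,
    noise_sd: float = 0.0,
    decoy_peaks_per_spectrum: int = 0,
    ion_mixture: dict[str, float] | None = None,
    seed: int = 0,
    enzyme: str = "trypsin",
    t_vm: float = 1.0,
    peak_cap: int = 400,
    true_peaks_only: bool = False,
    n_free_cys: int = 1,
) -> SyntheticDataset:
    """Plant ``n_bonds`` inter-peptide disulfide bonds in a random protein.

    The protein is a concatenation of tryptic peptides (random bodies
    terminated by K/R); 2*n_bonds of them carry one bonded cysteine
    each, and ``n_free_cys`` further peptides carry an unbonded cysteine
    (so negative cysteine pairs exist for specificity accounting).  For
    every planted bond one precursor mass (structure mass plus Gaussian
    noise) and one spectrum are emitted.  Spectrum peaks are the singly
    protonated theoretical fragment-structure m/z values of the bonded
    pair, intensities uniform on [0.2, 1], optionally thinned by
    per-ion-type ``ion_mixture`` weights; decoy peaks land at uniform
    random m/z excluded from +-t_vm of every theoretical mass.  The
    dataset is a deterministic function of the seed.
    """
    rng = np.random.default_rng(seed)
    n_cys_pep = 2 * n_bonds + n_free_cys
    n_pep = max(n_cys_pep + 1, round(protein_length / 9))
    if n_bonds < 1:
        raise ValueError("need at least one planted bond")
    lengths = rng.integers(6, 11, size=n_pep)
    bodies = [
        "".join(rng.choice(list(_BODY_RESIDUES), size=n - 1)) for n in lengths
    ]
    chosen = rng.choice(n_pep, size=n_cys_pep, replace=False)
    cys_peptides = chosen[: 2 * n_bonds]
    for idx in chosen:
        body = list(bodies[idx])
        body[rng.integers(1, len(body))] = "C"
        bodies[idx] = "".join(body)
    terminator = "K" if enzyme == "trypsin" else "F"
    protein = "".join(b + terminator for b in bodies)
    peptides = digest(protein, enzyme, 0)
    by_start = {p.start: p for p in peptides}

    starts = np.cumsum([0] + [len(b) + 1 for b in bodies[:-1]])
    order = rng.permutation(2 * n_bonds)
    structures: list[DisulfideStructure] = []
    topology: set[score_mod.CysPair] = set()
    pms: list[float] = []
    spectra: list[Spectrum] = []
    for b in range(n_bonds):
        i, j = cys_peptides[order[2 * b]], cys_peptides[order[2 * b + 1]]
        p1, p2 = by_start[starts[i]], by_start[starts[j]]
        bond = (((0, p1.cys_positions[0]), (1, p2.cys_positions[0])),)
        structure = DisulfideStructure(
            peptides=(p1, p2), n_bonds=1,
            mass=structure_mass([p1.mass, p2.mass], 1),
            bonded_pairs=bond,
        )
        structures.append(structure)
        topology.add(tuple(sorted((p1.start + p1.cys_positions[0] + 1,
                                   p2.start + p2.cys_positions[0] + 1))))
        pms.append(structure.mass + rng.normal(0.0, noise_sd) if noise_sd else structure.mass)
        spectra.append(_simulate_spectrum(
            structure, rng, ion_mixture, decoy_peaks_per_spectrum, t_vm,
            peak_cap, true_peaks_only,
        ))
    return SyntheticDataset(
        protein=protein, topology=topology, pms=pms, spectra=spectra,
        structures=structures, seed=seed, peptides=peptides,
    )


def _simulate_spectrum(
    structure, rng, ion_mixture, n_decoys, t_vm, peak_cap, true_peaks_only
) -> Spectrum:
    frag_structs = fms_mod.enumerate_fragment_structures(structure)
    masses = sorted({round(s.neutral_mass, 4) for s in frag_structs})
    peaks: list[tuple[float, float]] = []
    if not true_peaks_only:
        weights = None
        if ion_mixture:
            weights = {t: float(ion_mixture.get(t, 0.0)) for t in fms_mod.ION_TYPES}
            weights["intact"] = 1.0
        kept_masses = []
        by_mass: dict[float, list] = {}
        for s in frag_structs:
            by_mass.setdefault(round(s.neutral_mass, 4), []).append(s)
        for m in masses:
            if weights is not None:
                w = max(
                    float(np.mean([weights.get(f.ion_type, 0.0) for f in s.components]))
                    for s in by_mass[m]
                )
                if rng.random() >= w:
                    continue
            kept_masses.append(m)
        if len(kept_masses) > peak_cap:
            kept_masses = list(rng.choice(kept_masses, size=peak_cap, replace=False))
        peaks = [(m + PROTON, float(rng.uniform(0.2, 1.0))) for m in sorted(kept_masses)]
    theoretical = np.array(masses)
    lo, hi = 100.0, structure.mass + 50.0
    added = 0
    while added < n_decoys:
        m = float(rng.uniform(lo, hi))
        if np.min(np.abs(theoretical - m)) <= t_vm:
            continue
        peaks.append((m + PROTON, float(rng.uniform(0.2, 1.0))))
        added += 1
    peaks.sort()
    return Spectrum(precursor_mass=structure.mass, peaks=peaks,
                    title=structure.name)
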