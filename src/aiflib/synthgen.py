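"""Ground-truthed synthetic AIF data generator.

Emulates the acquisition design used for characterizing chemical
standards on a 15-minute HILIC gradient: 7-level 4-fold dilution series
(4.0 µM down to ~0.001 µM, 1–8000 fmol injected), three alternating
collision-energy channels (full scan, 10, 30 eV) at 6 scans/s (two
cycles per second, 1800 cycles per run), Gaussian elution peaks with a
saturating detector response, multiple adducts with carbon-13
isotopologues, energy-specific fragment tables, a constant contaminant
ion (default 149.0233 Th, the phthalic-anhydride background), additive
noise at a stated floor, sub-2-mDa mass jitter, and a smooth monotone
retention-time drift per run.

Every run is emitted together with a :class:`GroundTruthManifest`
written from the same source of truth, so downstream recovery tests can
compare deconvolution output against what was actually generated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .chem import (
    C13_C12_DELTA,
    ELECTRON_MASS,
    ElementalFormula,
    adduct_mz,
    monoisotopic_mass,
    parse_adduct,
    parse_formula,
)
from .rt_align import TISAnchor
from .spectra import AIFRun, Cycle, Scan

__all__ = [
    "SyntheticCompound",
    "compound_to_dict",
    "compound_from_dict",
    "save_compound_specs",
    "load_compound_specs",
    "GroundTruthManifest",
    "CompoundTruth",
    "Campaign",
    "make_dilution_series",
    "simulate_run",
    "simulate_characterization_campaign",
    "simulate_query_dataset",
    "synthetic_inchikey",
    "default_compounds",
    "default_tis",
    "linear_drift",
]

FragmentSpec = tuple[Union[str, float], float]  # (ion formula or m/z, rel %)

#: Fraction of the precursor ion surviving the collision cell per channel.
PRECURSOR_SURVIVAL = {0.0: 1.0, 10.0: 0.55, 30.0: 0.15}
#: Scale of the fragment budget (vs full-scan precursor apex) per channel.
FRAGMENT_SCALE = {0.0: 0.0, 10.0: 0.45, 30.0: 0.75}
#: Natural 13C abundance per carbon atom.
C13_RATIO = 0.0107

DEFAULT_ADDUCT_ABUNDANCES = {"[M+H]+": 0.80, "[M+Na]+": 0.15, "[M+K]+": 0.05}


def synthetic_inchikey(name: str) -> str:
    """A structurally valid but fabricated InChIKey, deterministic in ``name``.

    These keys have the 14-10-1 block shape so grouping and I/O behave as
    with real keys, but they are NOT derived from any structure and must
    not be resolved against chemical databases.
    """
    digest = hashlib.sha256(name.encode()).hexdigest().upper()
    letters = "".join(chr(ord("A") + int(c, 16) % 26) for c in digest)
    return f"{letters[:14]}-{letters[14:24]}-N"


def linear_drift(offset: float, slope: float = 0.0) -> Callable[[float], float]:
    """A smooth monotone RT perturbation: rt -> rt*(1+slope) + offset."""
    if slope <= -1:
        raise ValueError("slope must be > -1 for a monotone drift")
    return lambda rt: rt * (1.0 + slope) + offset


@dataclass
class SyntheticCompound:
    """A stated compound: identity, elution, ionization and fragmentation.

    ``fragments`` maps collision energy to (ion formula or literal m/z,
    relative intensity in (0, 100]) pairs. ``response`` is apex counts
    per fmol injected (the saturation ceiling clips above it).
    ``precursor_mz_override`` lets decoys sit at an arbitrary m/z
    without a consistent formula.
    """

    name: str
    rt: float
    response: float
    formula: Optional[ElementalFormula] = None
    inchikey: str = ""
    smiles: str = ""
    adduct_abundances: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADDUCT_ABUNDANCES)
    )
    fragments: Mapping[float, Sequence[FragmentSpec]] = field(default_factory=dict)
    precursor_mz_override: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if sum(self.adduct_abundances.values()) > 1.0 + 1e-9:
            raise ValueError(f"{self.name}: adduct fractions sum above 1")
        for energy, table in self.fragments.items():
            for ion, rel in table:
                if not (0 < rel <= 100):
                    raise ValueError(
                        f"{self.name}: fragment intensity {rel} outside (0, 100]"
                    )
        if not self.inchikey:
            self.inchikey = synthetic_inchikey(self.name)

    @property
    def primary_adduct(self) -> str:
        return max(self.adduct_abundances, key=lambda k: self.adduct_abundances[k])

    def adduct_ion_mz(self, adduct_name: str) -> float:
        if self.precursor_mz_override is not None:
            base = parse_adduct(self.primary_adduct)
            target = parse_adduct(adduct_name)
            delta = (target.net_formula_shift - target.charge * ELECTRON_MASS) - (
                base.net_formula_shift - base.charge * ELECTRON_MASS
            )
            return self.precursor_mz_override + delta
        if self.formula is None:
            raise ValueError(f"{self.name}: no formula and no m/z override")
        return adduct_mz(self.formula, parse_adduct(adduct_name))

    @property
    def precursor_mz(self) -> float:
        return self.adduct_ion_mz(self.primary_adduct)

    def fragment_mz(self, ion: Union[str, float]) -> float:
        """Fragment ion m/z: a literal value, or a cation composition."""
        if isinstance(ion, (int, float)):
            return float(ion)
        return monoisotopic_mass(parse_formula(ion)) - ELECTRON_MASS

    def carbon_count(self) -> int:
        return self.formula.get("C") if self.formula is not None else 0


@dataclass
class CompoundTruth:
    """What one compound actually looks like in one emitted run."""

    name: str
    amount_fmol: float
    apex_rt: float  # after drift
    adduct_heights: dict[str, float]
    fragment_tables: dict[float, list[tuple[float, float]]]  # energy -> (mz, apex)
    is_decoy: bool = False
    suppressed: bool = False


@dataclass
class GroundTruthManifest:
    run_id: str
    noise_floor: float
    compounds: dict[str, CompoundTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (CompoundTruth,)):
                return o.__dict__
            raise TypeError(type(o))

        return json.dumps(self.__dict__, default=enc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        raw = json.loads(text)
        compounds = {
            k: CompoundTruth(
                name=v["name"],
                amount_fmol=v["amount_fmol"],
                apex_rt=v["apex_rt"],
                adduct_heights=v["adduct_heights"],
                fragment_tables={
                    float(e): [tuple(t) for t in tbl]
                    for e, tbl in v["fragment_tables"].items()
                },
                is_decoy=v.get("is_decoy", False),
                suppressed=v.get("suppressed", False),
            )
            for k, v in raw["compounds"].items()
        }
        return cls(run_id=raw["run_id"], noise_floor=raw["noise_floor"], compounds=compounds)


def make_dilution_series(
    level_count: int = 7,
    fold: float = 4.0,
    top_conc: float = 4.0,
    volume_ul: Union[float, Sequence[float]] = 2.0,
) -> list[tuple[float, float]]:
    """(concentration µM, injected amount fmol) per dilution level.

    c_k = top_conc / fold**k for k = 0..level_count-1; the injected
    amount is concentration × volume (1 µL at 1 µM = 1000 fmol).
    """
    if level_count < 2:
        raise ValueError("level_count must be >= 2")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    volumes = (
        [float(volume_ul)] * level_count
        if np.ndim(volume_ul) == 0
        else list(volume_ul)
    )
    out = []
    for k in range(level_count):
        conc = top_conc / fold**k
        out.append((conc, conc * volumes[k] * 1000.0))
    return out


def _gaussian_support(
    times: np.ndarray, apex_rt: float, sigma_min: float, n_sigma: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(times, apex_rt - n_sigma * sigma_min)
    hi = np.searchsorted(times, apex_rt + n_sigma * sigma_min)
    idx = np.arange(lo, hi)
    vals = np.exp(-0.5 * ((times[idx] - apex_rt) / sigma_min) ** 2)
    return idx, vals


def simulate_run(
    compounds: Sequence[SyntheticCompound],
    amounts: Sequence[float],
    drift: Optional[Callable[[float], float]] = None,
    noise_floor: float = 100.0,
    seed: int = 0,
    *,
    gradient_min: float = 15.0,
    scan_rate: float = 6.0,
    channels: tuple[float, ...] = (0.0, 10.0, 30.0),
    sigma_s: float = 3.0,
    saturation: float = 5.0e6,
    mass_range: tuple[float, float] = (40.0, 1200.0),
    contaminant_ions: Sequence[tuple[float, float]] = ((149.0233, 20.0),),
    noise_ions_per_scan: int = 2,
    run_id: str = "",
    suppressed_names: Sequence[str] = (),
) -> tuple[AIFRun, GroundTruthManifest]:
    """Emit one AIF run plus its manifest; deterministic for a given seed.

    ``contaminant_ions`` are (m/z, multiple-of-noise-floor) pairs present
    at constant intensity in every scan of every channel. Compounds named
    in ``suppressed_names`` have all their ion heights halved (ion
    suppression by a coeluting analyte).
    """
    if len(compounds) != len(amounts):
        raise ValueError("compounds and amounts differ in length")
    rng = np.random.default_rng(seed)
    drift = drift or (lambda rt: rt)
    n_channels = len(channels)
    cycle_period_min = n_channels / scan_rate / 60.0
    n_cycles = int(round(gradient_min / cycle_period_min))
    sigma_min = sigma_s / 60.0
    # per-channel scan-time grids
    ch_times = {
        ch: (np.arange(n_cycles) * cycle_period_min + k / scan_rate / 60.0)
        for k, ch in enumerate(channels)
    }

    # (channel, cycle) -> [mz values], [intensities]
    buckets_mz: dict[tuple[float, int], list[np.ndarray]] = {}
    buckets_in: dict[tuple[float, int], list[np.ndarray]] = {}

    def emit(ch: float, idx: np.ndarray, mz: float, vals: np.ndarray) -> None:
        if not (mass_range[0] <= mz <= mass_range[1]):
            return
        jitterd = vals + rng.normal(0.0, 0.05 * noise_floor, vals.size)
        keep = jitterd > 0
        for j, v in zip(idx[keep], np.minimum(jitterd[keep], saturation)):
            key = (ch, int(j))
            buckets_mz.setdefault(key, []).append(np.array([mz]))
            buckets_in.setdefault(key, []).append(np.array([v]))

    manifest = GroundTruthManifest(run_id=run_id, noise_floor=noise_floor)

    for comp, amount in zip(compounds, amounts):
        apex_rt_true = comp.rt
        apex_rt = drift(apex_rt_true)
        if not (0 < apex_rt < gradient_min):
            raise ValueError(
                f"{comp.name}: drifted RT {apex_rt:.2f} outside the gradient"
            )
        suppressed = comp.name in suppressed_names
        base_height = comp.response * amount * (0.5 if suppressed else 1.0)
        mass_jitter = float(np.clip(rng.normal(0.0, 0.0007), -0.002, 0.002))

        adduct_heights: dict[str, float] = {}
        fragment_tables: dict[float, list[tuple[float, float]]] = {}
        primary_apex = 0.0
        for adduct_name, fraction in comp.adduct_abundances.items():
            h = min(base_height * fraction, saturation)
            adduct_heights[adduct_name] = h
            if adduct_name == comp.primary_adduct:
                primary_apex = h

        for ch in channels:
            times = ch_times[ch]
            survival = PRECURSOR_SURVIVAL.get(ch, 0.1)
            # adducts + first 13C isotopologue
            for adduct_name, h in adduct_heights.items():
                h_ch = h * survival
                if h_ch <= 0:
                    continue
                mz = comp.adduct_ion_mz(adduct_name) + mass_jitter
                idx, prof = _gaussian_support(times, apex_rt, sigma_min)
                emit(ch, idx, mz, h_ch * prof)
                n_c = comp.carbon_count()
                if n_c > 0:
                    emit(ch, idx, mz + C13_C12_DELTA, h_ch * prof * C13_RATIO * n_c)
            # collision-induced fragments
            scale = FRAGMENT_SCALE.get(ch, 0.0)
            table: list[tuple[float, float]] = []
            if scale > 0:
                for ion, rel in comp.fragments.get(ch, ()):
                    mz = comp.fragment_mz(ion) + mass_jitter
                    h_frag = min(rel / 100.0 * primary_apex * scale, saturation)
                    if h_frag <= 0:
                        continue
                    idx, prof = _gaussian_support(times, apex_rt, sigma_min)
                    emit(ch, idx, mz, h_frag * prof)
                    table.append((mz, h_frag))
            if table:
                fragment_tables[ch] = table
        # full-scan "fragment table" = the adduct/isotope pattern
        fragment_tables[0.0] = [
            (comp.adduct_ion_mz(a) + mass_jitter, h)
            for a, h in adduct_heights.items()
            if h > 0
        ]

        manifest.compounds[comp.name] = CompoundTruth(
            name=comp.name,
            amount_fmol=float(amount),
            apex_rt=float(apex_rt),
            adduct_heights=adduct_heights,
            fragment_tables=fragment_tables,
            is_decoy=comp.precursor_mz_override is not None,
            suppressed=suppressed,
        )

    # constant contaminants (chemical background, no chromatographic shape)
    for mz, mult in contaminant_ions:
        for ch in channels:
            level = mult * noise_floor
            vals = level * (1.0 + rng.normal(0.0, 0.03, n_cycles))
            for j in range(n_cycles):
                key = (ch, j)
                buckets_mz.setdefault(key, []).append(np.array([mz]))
                buckets_in.setdefault(key, []).append(np.array([max(vals[j], 0.0)]))

    # random noise centroids at the floor
    if noise_ions_per_scan > 0:
        for ch in channels:
            mzs = rng.uniform(mass_range[0], mass_range[1], (n_cycles, noise_ions_per_scan))
            ints = np.abs(rng.normal(noise_floor, noise_floor / 3.0, (n_cycles, noise_ions_per_scan)))
            for j in range(n_cycles):
                key = (ch, j)
                buckets_mz.setdefault(key, []).append(mzs[j])
                buckets_in.setdefault(key, []).append(ints[j])

    cycles = []
    for j in range(n_cycles):
        scans = {}
        for ch in channels:
            key = (ch, j)
            if key in buckets_mz:
                mz = np.concatenate(buckets_mz[key])
                inten = np.concatenate(buckets_in[key])
            else:
                mz = np.array([])
                inten = np.array([])
            scans[ch] = Scan(time=float(ch_times[ch][j]), energy=ch, mz=mz, intensity=inten)
        cycles.append(Cycle(scans=scans))

    run = AIFRun(
        cycles=cycles,
        channel_energies=tuple(channels),
        mass_range=mass_range,
        run_id=run_id,
    )
    return run, manifest


@dataclass
class Campaign:
    """A full characterization campaign: per-compound dilution series with
    tIS spiked into every run, plus blanks (tIS only)."""

    series: dict[str, list[AIFRun]]
    manifests: dict[str, list[GroundTruthManifest]]
    blanks: dict[str, AIFRun]
    blank_manifests: dict[str, GroundTruthManifest]
    tis: list[TISAnchor]
    compounds: dict[str, SyntheticCompound]
    tis_compounds: list[SyntheticCompound]
    noise_floor: float
    amounts: list[float]


def simulate_characterization_campaign(
    compound_specs: Sequence[SyntheticCompound],
    tis_specs: Sequence[SyntheticCompound],
    seed: int = 0,
    *,
    level_count: int = 7,
    fold: float = 4.0,
    top_conc: float = 4.0,
    volume_ul: float = 2.0,
    tis_amount_fmol: float = 500.0,
    noise_floor: float = 100.0,
    suppress_coeluting_tis: bool = False,
    coelution_window: float = 0.25,
    include_blanks: bool = True,
    max_drift_offset: float = 0.3,
    max_drift_slope: float = 0.02,
    **run_kw,
) -> Campaign:
    """Per-compound 7-level dilution series (plus a blank between
    compounds), tIS at constant amount in every run, per-run smooth drift.

    With ``suppress_coeluting_tis``, any tIS eluting within
    ``coelution_window`` minutes of the analyte has its height halved in
    that compound's runs (ion suppression).
    """
    if len(tis_specs) < 2:
        raise ValueError("need >= 2 tIS spanning the gradient")
    rng = np.random.default_rng(seed)
    levels = make_dilution_series(level_count, fold, top_conc, volume_ul)
    tis_list = list(tis_specs)
    anchors = [
        TISAnchor(
            name=t.name,
            reference_rt=t.rt,
            formula=t.formula,
            adduct=parse_adduct(t.primary_adduct),
        )
        for t in tis_list
    ]

    series: dict[str, list[AIFRun]] = {}
    manifests: dict[str, list[GroundTruthManifest]] = {}
    blanks: dict[str, AIFRun] = {}
    blank_manifests: dict[str, GroundTruthManifest] = {}

    for comp in compound_specs:
        suppressed = [
            t.name
            for t in tis_list
            if suppress_coeluting_tis and abs(t.rt - comp.rt) <= coelution_window
        ]
        runs: list[AIFRun] = []
        mans: list[GroundTruthManifest] = []
        for k, (conc, amount) in enumerate(levels):
            offset = rng.uniform(-max_drift_offset, max_drift_offset)
            slope = rng.uniform(-max_drift_slope, max_drift_slope)
            run_seed = int(rng.integers(0, 2**31 - 1))
            run, man = simulate_run(
                [comp, *tis_list],
                [amount] + [tis_amount_fmol] * len(tis_list),
                drift=linear_drift(offset, slope),
                noise_floor=noise_floor,
                seed=run_seed,
                run_id=f"{comp.name}/L{k}",
                suppressed_names=suppressed,
                **run_kw,
            )
            runs.append(run)
            mans.append(man)
        series[comp.name] = runs
        manifests[comp.name] = mans
        if include_blanks:
            offset = rng.uniform(-max_drift_offset, max_drift_offset)
            slope = rng.uniform(-max_drift_slope, max_drift_slope)
            run_seed = int(rng.integers(0, 2**31 - 1))
            run, man = simulate_run(
                tis_list,
                [tis_amount_fmol] * len(tis_list),
                drift=linear_drift(offset, slope),
                noise_floor=noise_floor,
                seed=run_seed,
                run_id=f"blank/{comp.name}",
                **run_kw,
            )
            blanks[comp.name] = run
            blank_manifests[comp.name] = man

    return Campaign(
        series=series,
        manifests=manifests,
        blanks=blanks,
        blank_manifests=blank_manifests,
        tis=anchors,
        compounds={c.name: c for c in compound_specs},
        tis_compounds=tis_list,
        noise_floor=noise_floor,
        amounts=[a for _, a in levels],
    )


def simulate_query_dataset(
    library_truth: Sequence[SyntheticCompound],
    decoy_specs: Optional[Sequence[SyntheticCompound]] = None,
    seed: int = 0,
    *,
    tis_specs: Sequence[SyntheticCompound] = (),
    amount_fmol: float = 500.0,
    tis_amount_fmol: float = 500.0,
    noise_floor: float = 100.0,
    max_drift_offset: float = 0.2,
    **run_kw,
) -> tuple[AIFRun, GroundTruthManifest]:
    """A query run: the true compound(s) plus same-m/z decoys at other RTs.

    Default decoys mimic the urine-study situation: two features in the
    true compound's m/z window, at distinct retention times, whose
    fragment sets are disjoint from the true compound's — an AMRT match
    alone cannot tell them apart.
    """
    rng = np.random.default_rng(seed)
    truths = list(library_truth)
    if decoy_specs is None:
        decoy_specs = default_decoys(
            truths[0], gradient_min=run_kw.get("gradient_min", 15.0)
        )
    compounds = truths + list(decoy_specs) + list(tis_specs)
    amounts = (
        [amount_fmol] * len(truths)
        + [amount_fmol * 1.5] * len(decoy_specs)
        + [tis_amount_fmol] * len(tis_specs)
    )
    offset = rng.uniform(-max_drift_offset, max_drift_offset)
    run_seed = int(rng.integers(0, 2**31 - 1))
    return simulate_run(
        compounds,
        amounts,
        drift=linear_drift(offset),
        noise_floor=noise_floor,
        seed=run_seed,
        run_id="query",
        **run_kw,
    )


def default_decoys(
    true_comp: SyntheticCompound, gradient_min: float = 15.0
) -> list[SyntheticCompound]:
    """Two decoys sharing the true compound's precursor m/z, at other RTs,
    with disjoint fragment sets (in-source fragments / unknowns).

    On the standard 15-minute gradient the decoys elute at 4.99 and
    6.58 min; on a shorter gradient they scale to 55%% and 80%% of the
    true compound's RT so the scenario stays well-formed.
    """
    mz = true_comp.precursor_mz
    rt_early, rt_late = 4.99, 6.58
    if rt_late >= min(gradient_min, true_comp.rt + 7.0) or rt_early >= true_comp.rt:
        rt_early, rt_late = 0.55 * true_comp.rt, 0.80 * true_comp.rt
    return [
        SyntheticCompound(
            name="decoy-early",
            rt=rt_early,
            response=3000.0,
            precursor_mz_override=mz,
            adduct_abundances={"[M+H]+": 1.0},
            fragments={
                10.0: [(70.0651, 100.0), (96.0808, 40.0)],
                30.0: [(53.0386, 100.0), (70.0651, 70.0), (121.0508, 30.0)],
            },
        ),
        SyntheticCompound(
            name="decoy-late",
            rt=rt_late,
            response=2500.0,
            precursor_mz_override=mz,
            adduct_abundances={"[M+H]+": 1.0},
            fragments={
                10.0: [(58.0651, 100.0), (104.0712, 45.0)],
                30.0: [(42.0338, 100.0), (58.0651, 65.0), (91.0542, 25.0)],
            },
        ),
    ]


def default_compounds() -> list[SyntheticCompound]:
    """Five hydrophilic standards with realistic HILIC behavior.

    Three of them share the C7H7NO2 formula (trigonelline plus two
    aminobenzoate-like isomers at distinct retention times), mirroring
    the situation where accurate mass alone cannot separate isomers and
    the library must hold same-m/z records at several RTs. Trigonelline
    carries a positively charged nitrogen and ionizes about an order of
    magnitude better than the amino acids. Fragment tables are
    subformula ions of each protonated molecule so that formula
    annotation succeeds on clean deconvoluted spectra.
    """
    return [
        SyntheticCompound(
            name="trigonelline",
            formula=parse_formula("C7H7NO2"),
            rt=7.46,
            response=7000.0,
            smiles="C[n+]1cccc(c1)C(=O)[O-]",
            fragments={
                10.0: [("C7H6NO", 35.0), ("C6H8N", 20.0)],
                30.0: [("C6H8N", 100.0), ("C5H6N", 45.0), ("C3H4N", 12.0)],
            },
        ),
        SyntheticCompound(
            name="2-aminobenzoic acid",
            formula=parse_formula("C7H7NO2"),
            rt=5.02,
            response=800.0,
            smiles="Nc1ccccc1C(=O)O",
            fragments={
                10.0: [("C7H6NO", 55.0), ("C6H6N", 20.0)],
                30.0: [("C7H6NO", 100.0), ("C6H6N", 60.0), ("C5H6N", 10.0)],
            },
        ),
        SyntheticCompound(
            name="4-aminobenzoic acid",
            formula=parse_formula("C7H7NO2"),
            rt=6.61,
            response=950.0,
            smiles="Nc1ccc(cc1)C(=O)O",
            fragments={
                10.0: [("C7H6NO", 45.0), ("C6H8N", 15.0)],
                30.0: [("C6H8N", 100.0), ("C7H6NO", 75.0), ("C6H6N", 25.0)],
            },
        ),
        SyntheticCompound(
            name="valine",
            formula=parse_formula("C5H11NO2"),
            rt=7.21,
            response=900.0,
            smiles="CC(C)C(N)C(=O)O",
            fragments={
                10.0: [("C4H10N", 60.0), ("C5H10NO", 25.0)],
                30.0: [("C4H10N", 100.0), ("C3H6N", 30.0), ("C2H6N", 18.0)],
            },
        ),
        SyntheticCompound(
            name="betaine",
            formula=parse_formula("C5H11NO2"),
            rt=7.41,
            response=5500.0,
            smiles="C[N+](C)(C)CC(=O)[O-]",
            fragments={
                10.0: [("C4H10N", 40.0), ("C3H8N", 15.0)],
                30.0: [("C3H8N", 100.0), ("C4H10N", 55.0), ("C2H6N", 20.0)],
            },
        ),
    ]


def default_tis() -> list[SyntheticCompound]:
    """Five technical internal standards spanning the 15-minute gradient."""
    specs = [
        ("tIS-early", "C9H11NO2", 1.50, 2600.0),  # aromatic amino-acid-like, weakly retained
        ("tIS-mid1", "C6H13NO2", 4.40, 1200.0),
        ("tIS-mid2", "C3H7NO3", 7.90, 1000.0),
        ("tIS-late1", "C2H7NO3S", 10.60, 800.0),
        ("tIS-late2", "C6H14N2O2", 13.40, 1500.0),
    ]
    out = []
    for name, formula, rt, response in specs:
        out.append(
            SyntheticCompound(
                name=name,
                formula=parse_formula(formula),
                rt=rt,
                response=response,
                adduct_abundances={"[M+H]+": 0.9},
                fragments={},
            )
        )
    return out


# ---------------------------------------------------------------------------
# human-editable spec files (YAML)
# ---------------------------------------------------------------------------

def compound_to_dict(c: SyntheticCompound) -> dict:
    return {
        "name": c.name,
        "formula": str(c.formula) if c.formula is not None else None,
        "rt": c.rt,
        "response": c.response,
        "inchikey": c.inchikey,
        "smiles": c.smiles,
        "adducts": dict(c.adduct_abundances),
        "fragments": {
            float(e): [[ion, rel] for ion, rel in table]
            for e, table in c.fragments.items()
        },
        "precursor_mz_override": c.precursor_mz_override,
    }


def compound_from_dict(d: dict) -> SyntheticCompound:
    return SyntheticCompound(
        name=d["name"],
        formula=parse_formula(d["formula"]) if d.get("formula") else None,
        rt=float(d["rt"]),
        response=float(d["response"]),
        inchikey=d.get("inchikey", ""),
        smiles=d.get("smiles", ""),
        adduct_abundances=d.get("adducts", dict(DEFAULT_ADDUCT_ABUNDANCES)),
        fragments={
            float(e): [(ion, float(rel)) for ion, rel in table]
            for e, table in d.get("fragments", {}).items()
        },
        precursor_mz_override=d.get("precursor_mz_override"),
    )


def save_compound_specs(path, compounds, tis=()) -> None:
    import yaml

    data = {
        "compounds": [compound_to_dict(c) for c in compounds],
        "tis": [compound_to_dict(t) for t in tis],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_compound_specs(path) -> tuple[list[SyntheticCompound], list[SyntheticCompound]]:
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    compounds = [compound_from_dict(d) for d in data.get("compounds", [])]
    tis = [compound_from_dict(d) for d in data.get("tis", [])]
    return compounds, tis
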