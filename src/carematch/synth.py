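"""Seeded synthetic registry and population samples.

Emulates the statistical structure of routine address data: a regulator's
registry (with cancelled predecessors and ineligible services), population
samples at configurable care-home prevalence, address noise (typos,
abbreviations, dropped lines, blank postcodes), private households sharing
a care-home postcode, historic care-home names, and an institution flag of
configurable sensitivity and false-positive rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import grammar
from .address import MISSING, RawAddress, canonicalize_postcode
from .matchers import AddressRecord
from .registry import (
    STATUS_ACTIVE,
    STATUS_CANCELLED,
    CareHomeService,
    EligibilityRules,
    Registry,
    eligible_services,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticSample",
    "PRESETS",
    "generate_registry",
    "perturb_address",
    "generate_sample",
    "write_sample",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All rates and sizes driving one synthetic sample; seed fixes the
    entire output stream."""

    n_records: int = 5000
    prevalence: float = 0.086
    n_homes: int = 40
    cancelled_fraction: float = 0.2
    ineligible_fraction: float = 0.15
    typo_rate: float = 0.25
    abbreviation_rate: float = 0.30
    dropped_line_rate: float = 0.15
    missing_postcode_rate: float = 0.03
    shared_postcode_rate: float = 0.015
    historic_name_rate: float = 0.10
    flag_sensitivity: float = 0.893
    flag_false_rate: float = 0.00198
    board: str = "TAYSIDE"
    sample: str = "default"
    seed: int = 0

    def __post_init__(self):
        rates = {
            "prevalence": self.prevalence,
            "cancelled_fraction": self.cancelled_fraction,
            "ineligible_fraction": self.ineligible_fraction,
            "typo_rate": self.typo_rate,
            "abbreviation_rate": self.abbreviation_rate,
            "dropped_line_rate": self.dropped_line_rate,
            "missing_postcode_rate": self.missing_postcode_rate,
            "shared_postcode_rate": self.shared_postcode_rate,
            "historic_name_rate": self.historic_name_rate,
            "flag_sensitivity": self.flag_sensitivity,
            "flag_false_rate": self.flag_false_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {value}")
        if self.n_records <= 0:
            raise ValueError("n_records must be > 0")
        if self.n_homes < 1:
            raise ValueError("n_homes must be >= 1")


# Four presets shaped on published population samples: prevalence is the
# observed care-home proportion; flag_sensitivity the printed flag
# sensitivity; flag_false_rate implies the printed flag PPV at that
# prevalence (ppv = sens*prev / (sens*prev + ffr*(1-prev))).
PRESETS: dict[str, GeneratorConfig] = {
    "fife_population": GeneratorConfig(
        prevalence=0.0426, flag_sensitivity=0.558, flag_false_rate=0.000200,
        board="FIFE", sample="fife_population", seed=11,
    ),
    "tayside_population": GeneratorConfig(
        prevalence=0.0506, flag_sensitivity=0.597, flag_false_rate=0.000616,
        board="TAYSIDE", sample="tayside_population", seed=12,
    ),
    "fife_over65": GeneratorConfig(
        prevalence=0.1112, flag_sensitivity=0.586, flag_false_rate=0.000294,
        board="FIFE", sample="fife_over65", seed=13,
    ),
    "tayside_over65": GeneratorConfig(
        prevalence=0.0862, flag_sensitivity=0.893, flag_false_rate=0.00198,
        board="TAYSIDE", sample="tayside_over65", seed=14,
    ),
}


@dataclass
class SyntheticSample:
    records: list[AddressRecord]
    truth: dict[str, bool]
    registry: Registry
    provenance: dict[str, dict]
    config: GeneratorConfig


def _postcode(rng: np.random.Generator, area: str) -> str:
    district = int(rng.integers(1, 99))
    unit = "".join(
        chr(ord("A") + int(c)) for c in rng.integers(0, 26, size=2)
    )
    return f"{area}{district} {int(rng.integers(0, 10))}{unit}"


def _board_area(board: str) -> str:
    # two pseudo postcode-area letters derived from the board label
    letters = [c for c in board.upper() if c.isalpha()] or ["Z"]
    return (letters[0] + letters[-1])[:2]


def _fresh_postcode(rng, area, taken: set[str]) -> str:
    while True:
        pc = _postcode(rng, area)
        if canonicalize_postcode(pc) not in taken:
            taken.add(canonicalize_postcode(pc))
            return pc


def generate_registry(
    n_homes: int = 40,
    board: str = "TAYSIDE",
    cancelled_fraction: float = 0.2,
    seed: int = 0,
    ineligible_fraction: float = 0.15,
) -> Registry:
    """Registry of ``n_homes`` active eligible homes plus cancelled
    predecessors (same site, different name) and ineligible sheltered
    housing services. Fully determined by the seed."""
    rng = np.random.default_rng(seed)
    area = _board_area(board)
    taken: set[str] = set()
    services: list[CareHomeService] = []

    combos = [
        (stem, suffix)
        for stem in grammar.HOME_STEMS
        for suffix in grammar.HOME_SUFFIXES
    ]
    order = rng.permutation(len(combos))

    n_cancelled = int(round(cancelled_fraction * n_homes))
    n_ineligible = int(round(ineligible_fraction * n_homes))

    for i in range(n_homes):
        stem, suffix = combos[order[i] % len(combos)]
        service_type = grammar.SERVICE_TYPES[int(rng.integers(0, 2))]
        name = f"{stem} {suffix} {service_type}"
        street = f"{int(rng.integers(1, 200))} {grammar.STREET_STEMS[int(rng.integers(0, len(grammar.STREET_STEMS)))]} {grammar.STREET_TYPES[int(rng.integers(0, len(grammar.STREET_TYPES)))]}"
        town = grammar.TOWNS[int(rng.integers(0, len(grammar.TOWNS)))]
        pc = _fresh_postcode(rng, area, taken)
        services.append(
            CareHomeService(
                service_id=f"CS{i:04d}",
                name=name,
                address=RawAddress(lines=(name, street, town), postcode=pc),
                board=board,
                status=STATUS_ACTIVE,
                service_type=service_type,
                client_group="OLDER PEOPLE",
            )
        )

    # cancelled predecessors share the site address under an older name
    for j in range(n_cancelled):
        host = services[j]
        stem, suffix = combos[order[(n_homes + j) % len(order)] % len(combos)]
        old_type = grammar.SERVICE_TYPES[int(rng.integers(0, 2))]
        old_name = f"{stem} {suffix} {old_type}"
        services.append(
            CareHomeService(
                service_id=f"CX{j:04d}",
                name=old_name,
                address=RawAddress(
                    lines=(old_name,) + host.address.lines[1:],
                    postcode=host.address.postcode,
                ),
                board=board,
                status=STATUS_CANCELLED,
                service_type=old_type,
                client_group="OLDER PEOPLE",
            )
        )

    for k in range(n_ineligible):
        stem = grammar.HOME_STEMS[int(rng.integers(0, len(grammar.HOME_STEMS)))]
        name = f"{stem} SHELTERED HOUSING"
        town = grammar.TOWNS[int(rng.integers(0, len(grammar.TOWNS)))]
        pc = _fresh_postcode(rng, area, taken)
        services.append(
            CareHomeService(
                service_id=f"SH{k:04d}",
                name=name,
                address=RawAddress(
                    lines=(name, f"{int(rng.integers(1, 200))} {grammar.STREET_STEMS[int(rng.integers(0, len(grammar.STREET_STEMS)))]} {grammar.STREET_TYPES[int(rng.integers(0, len(grammar.STREET_TYPES)))]}", town),
                    postcode=pc,
                ),
                board=board,
                status=STATUS_ACTIVE,
                service_type="SHELTERED HOUSING",
                client_group="OLDER PEOPLE",
            )
        )
    return Registry(services)


def _apply_typo(text: str, rng: np.random.Generator) -> str:
    """One character-level swap, deletion or insertion at a random position."""
    if not text:
        return "X"
    op = int(rng.integers(0, 3))
    i = int(rng.integers(0, len(text)))
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if op == 0 and len(text) >= 2:  # swap adjacent (skip equal pairs: no-op)
        candidates = [j for j in range(len(text) - 1) if text[j] != text[j + 1]]
        if candidates:
            i = candidates[i % len(candidates)]
            return text[:i] + text[i + 1] + text[i] + text[i + 2:]
        op = 2
    if op == 1 and len(text) >= 2:  # delete
        return text[:i] + text[i + 1:]
    return text[:i] + letters[int(rng.integers(0, 26))] + text[i:]  # insert


def _apply_abbreviation(lines: list[str], rng: np.random.Generator) -> bool:
    """Substitute the first abbreviatable word found; returns success."""
    table = dict(grammar.ABBREVIATIONS)
    table.update({v: k for k, v in grammar.ABBREVIATIONS.items()})
    for idx, line in enumerate(lines):
        words = line.split()
        for w_idx, word in enumerate(words):
            if word.upper() in table:
                words[w_idx] = table[word.upper()]
                lines[idx] = " ".join(words)
                return True
    return False


def perturb_address(
    source: RawAddress,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[RawAddress, list[str]]:
    """Independently apply typo, abbreviation, line-drop and postcode-blank
    perturbations at their configured rates; returns the new address and
    the list of perturbations that fired."""
    lines = [ln for ln in source.lines]
    postcode = source.postcode
    applied: list[str] = []

    if rng.random() < config.typo_rate:
        nonempty = [i for i, ln in enumerate(lines) if ln.strip()]
        if nonempty:
            i = nonempty[int(rng.integers(0, len(nonempty)))]
            lines[i] = _apply_typo(lines[i], rng)
            applied.append("typo")
    if rng.random() < config.abbreviation_rate:
        if _apply_abbreviation(lines, rng):
            applied.append("abbreviation")
    if rng.random() < config.dropped_line_rate:
        droppable = [i for i in range(1, len(lines)) if lines[i].strip()]
        if droppable:
            del lines[droppable[int(rng.integers(0, len(droppable)))]]
            applied.append("dropped_line")
    if rng.random() < config.missing_postcode_rate:
        if postcode.strip():
            postcode = ""
            applied.append("missing_postcode")

    if not lines:
        lines = [""]
    return RawAddress(lines=tuple(lines), postcode=postcode), applied


def _private_address(rng, area, registry_postcodes, shared_pool, config):
    """A non-care-home household address; optionally on a care-home postcode."""
    number = int(rng.integers(1, 300))
    street = f"{grammar.STREET_STEMS[int(rng.integers(0, len(grammar.STREET_STEMS)))]} {grammar.STREET_TYPES[int(rng.integers(0, len(grammar.STREET_TYPES)))]}"
    town = grammar.TOWNS[int(rng.integers(0, len(grammar.TOWNS)))]
    shared = bool(shared_pool) and rng.random() < config.shared_postcode_rate
    if shared:
        pc = shared_pool[int(rng.integers(0, len(shared_pool)))]
    else:
        while True:
            pc = _postcode(rng, area)
            if canonicalize_postcode(pc) not in registry_postcodes:
                break
    if rng.random() < config.missing_postcode_rate:
        pc = ""
    return RawAddress(lines=(f"{number} {street}", town), postcode=pc), shared


def generate_sample(config: GeneratorConfig, registry: Registry) -> SyntheticSample:
    """Draw one population sample against a registry.

    Each record is a true care-home address with probability ``prevalence``;
    positives copy a uniformly chosen eligible active service address
    (historic predecessors swapped in at ``historic_name_rate``) then pass
    through ``perturb_address``. Negatives are grammar-built private
    households, placed on a care-home postcode at ``shared_postcode_rate``.
    Institution-flag codes are drawn per ``flag_sensitivity`` /
    ``flag_false_rate``.
    """
    rng = np.random.default_rng(config.seed)
    eligible_active = sorted(
        sid
        for sid in eligible_services(registry, include_cancelled=False)
        if registry[sid].status == STATUS_ACTIVE
    )
    if not eligible_active:
        raise ValueError("registry has no eligible active services to sample from")

    # map active home -> its cancelled predecessor on the same site, if any
    predecessors: dict[str, str] = {}
    for svc in registry.services:
        if svc.status != STATUS_CANCELLED:
            continue
        key = (canonicalize_postcode(svc.address.postcode), svc.address.lines[1:])
        for host in registry.services:
            if host.status == STATUS_ACTIVE and (
                canonicalize_postcode(host.address.postcode),
                host.address.lines[1:],
            ) == key:
                predecessors[host.service_id] = svc.service_id

    registry_pcs = set(registry.by_postcode)
    eligible_all = eligible_services(registry, include_cancelled=True)
    shared_pool = sorted(
        {
            registry[sid].address.postcode
            for sid in eligible_all
            if canonicalize_postcode(registry[sid].address.postcode) is not MISSING
        }
    )

    records: list[AddressRecord] = []
    truth: dict[str, bool] = {}
    provenance: dict[str, dict] = {}

    for i in range(config.n_records):
        rid = f"R{i:05d}"
        positive = bool(rng.random() < config.prevalence)
        note: dict = {"positive": positive}
        if positive:
            sid = eligible_active[int(rng.integers(0, len(eligible_active)))]
            svc = registry[sid]
            source = svc.address
            historic = False
            if sid in predecessors and rng.random() < config.historic_name_rate:
                old = registry[predecessors[sid]]
                source = RawAddress(
                    lines=(old.name,) + svc.address.lines[1:],
                    postcode=svc.address.postcode,
                )
                historic = True
            address, applied = perturb_address(source, config, rng)
            flag = (
                int(rng.choice([93, 98]))
                if rng.random() < config.flag_sensitivity
                else None
            )
            note.update(
                source_service=sid,
                historic_name=historic,
                perturbations=applied,
            )
        else:
            address, shared = _private_address(
                rng, _board_area(config.board), registry_pcs, shared_pool, config
            )
            flag = (
                int(rng.choice([93, 98]))
                if rng.random() < config.flag_false_rate
                else None
            )
            note.update(source_service=None, shared_postcode=shared)
        records.append(
            AddressRecord(
                record_id=rid,
                address=address,
                flag_code=flag,
                board=config.board,
                sample=config.sample,
            )
        )
        truth[rid] = positive
        provenance[rid] = note

    return SyntheticSample(records, truth, registry, provenance, config)


def write_sample(sample: SyntheticSample, outdir) -> dict[str, str]:
    """Write registry/population/truth CSVs plus a provenance JSON sidecar."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reg_rows = []
    for s in sample.registry.services:
        lines = list(s.address.lines[:3]) + [""] * (3 - len(s.address.lines[:3]))
        reg_rows.append(
            {
                "service_id": s.service_id,
                "name": s.name,
                "line1": lines[0],
                "line2": lines[1],
                "line3": lines[2],
                "postcode": s.address.postcode,
                "board": s.board,
                "status": s.status,
                "service_type": s.service_type,
                "client_group": s.client_group,
            }
        )
    pop_rows = []
    for r in sample.records:
        lines = list(r.address.lines[:5]) + [""] * (5 - len(r.address.lines[:5]))
        pop_rows.append(
            {
                "record_id": r.record_id,
                "line1": lines[0],
                "line2": lines[1],
                "line3": lines[2],
                "line4": lines[3],
                "line5": lines[4],
                "postcode": r.address.postcode,
                "flag_code": "" if r.flag_code is None else str(r.flag_code),
                "board": r.board,
                "sample": r.sample,
            }
        )
    truth_rows = [
        {"record_id": rid, "care_home": int(v)} for rid, v in sample.truth.items()
    ]

    paths = {
        "registry": str(outdir / "registry.csv"),
        "population": str(outdir / "population.csv"),
        "truth": str(outdir / "truth.csv"),
        "provenance": str(outdir / "provenance.json"),
    }
    pd.DataFrame(reg_rows).to_csv(paths["registry"], index=False)
    pd.DataFrame(pop_rows).to_csv(paths["population"], index=False)
    pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    with open(paths["provenance"], "w") as fh:
        json.dump(
            {"config": asdict(sample.config), "records": sample.provenance},
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths
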