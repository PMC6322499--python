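"""Care-home service registry: loading, eligibility filtering, indexes."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .address import MISSING, RawAddress, SchemaError, canonicalize_postcode

__all__ = [
    "CareHomeService",
    "Registry",
    "EligibilityRules",
    "load_registry",
    "eligible_services",
]

STATUS_ACTIVE = "active"
STATUS_CANCELLED = "cancelled"

REGISTRY_COLUMNS = (
    "service_id", "name", "line1", "line2", "line3",
    "postcode", "board", "status", "service_type", "client_group",
)


@dataclass(frozen=True)
class CareHomeService:
    service_id: str
    name: str
    address: RawAddress
    board: str
    status: str
    service_type: str
    client_group: str

    def __post_init__(self):
        if self.status not in (STATUS_ACTIVE, STATUS_CANCELLED):
            raise ValueError(f"status must be active/cancelled, got {self.status!r}")


@dataclass(frozen=True)
class EligibilityRules:
    """Controlled vocabularies deciding which services count as care homes.

    The regulator's service-type vocabulary is configurable rather than
    hard-coded; defaults cover the synthetic generator's output.
    """

    care_home_types: frozenset[str] = frozenset({"CARE HOME", "NURSING HOME"})
    older_people_groups: frozenset[str] = frozenset({"OLDER PEOPLE"})

    def is_eligible(self, service: CareHomeService) -> bool:
        return (
            service.service_type.strip().upper() in self.care_home_types
            and service.client_group.strip().upper() in self.older_people_groups
        )


class Registry:
    """Immutable collection of services with postcode and board indexes."""

    def __init__(self, services: list[CareHomeService]):
        ids = [s.service_id for s in services]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate service_id values: {dupes}")
        self.services = list(services)
        self._by_id = {s.service_id: s for s in services}
        self.by_postcode: dict[str, set[str]] = {}
        self.by_board: dict[str, set[str]] = {}
        for s in services:
            pc = canonicalize_postcode(s.address.postcode)
            if pc is not MISSING:
                self.by_postcode.setdefault(pc, set()).add(s.service_id)
            self.by_board.setdefault(s.board, set()).add(s.service_id)

    def __len__(self) -> int:
        return len(self.services)

    def __getitem__(self, service_id: str) -> CareHomeService:
        return self._by_id[service_id]

    def __contains__(self, service_id: str) -> bool:
        return service_id in self._by_id


def load_registry(path) -> Registry:
    """Load a registry CSV; raises SchemaError on missing columns."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"registry table missing required columns: {missing}")
    services = []
    for row in df.itertuples(index=False):
        services.append(
            CareHomeService(
                service_id=row.service_id,
                name=row.name,
                address=RawAddress(
                    lines=(row.line1, row.line2, row.line3),
                    postcode=row.postcode,
                ),
                board=row.board,
                status=row.status,
                service_type=row.service_type,
                client_group=row.client_group,
            )
        )
    return Registry(services)


def eligible_services(
    registry: Registry,
    include_cancelled: bool = True,
    rules: EligibilityRules = EligibilityRules(),
) -> set[str]:
    """Service ids registered as care homes for older people.

    Cancelled services are kept by default: historic care-home names stay
    in use on live address records long after deregistration.
    """
    out = set()
    for s in registry.services:
        if not rules.is_eligible(s):
            continue
        if s.status == STATUS_CANCELLED and not include_cancelled:
            continue
        out.add(s.service_id)
    return out
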