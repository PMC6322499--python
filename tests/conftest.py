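import pytest

from carematch.address import RawAddress
from carematch.matchers import AddressRecord
from carematch.registry import CareHomeService, Registry


@pytest.fixture
def small_registry() -> Registry:
    """Two eligible homes (one per board), one sheltered-housing service and
    one cancelled predecessor sharing the first home's site."""
    return Registry(
        [
            CareHomeService(
                service_id="CS001",
                name="The Elms Care Home",
                address=RawAddress(
                    lines=("The Elms Care Home", "12 High Street", "Dunburgh"),
                    postcode="DD1 4HN",
                ),
                board="TAYSIDE",
                status="active",
                service_type="CARE HOME",
                client_group="OLDER PEOPLE",
            ),
            CareHomeService(
                service_id="CS002",
                name="Rowan Lodge Nursing Home",
                address=RawAddress(
                    lines=("Rowan Lodge Nursing Home", "3 Mill Road", "Kirkfield"),
                    postcode="KY2 9ZZ",
                ),
                board="FIFE",
                status="active",
                service_type="NURSING HOME",
                client_group="OLDER PEOPLE",
            ),
            CareHomeService(
                service_id="CX001",
                name="Birch House Care Home",
                address=RawAddress(
                    lines=("Birch House Care Home", "12 High Street", "Dunburgh"),
                    postcode="DD1 4HN",
                ),
                board="TAYSIDE",
                status="cancelled",
                service_type="CARE HOME",
                client_group="OLDER PEOPLE",
            ),
            CareHomeService(
                service_id="SH001",
                name="Oak Sheltered Housing",
                address=RawAddress(
                    lines=("Oak Sheltered Housing", "5 Glen Terrace", "Dunburgh"),
                    postcode="DD9 1AA",
                ),
                board="TAYSIDE",
                status="active",
                service_type="SHELTERED HOUSING",
                client_group="OLDER PEOPLE",
            ),
        ]
    )


@pytest.fixture
def elms_record() -> AddressRecord:
    """Record identical to CS001's address (different case/punctuation)."""
    return AddressRecord(
        record_id="R1",
        address=RawAddress(
            lines=("The Elms Care Home,", "12 High Street", "Dunburgh"),
            postcode="dd1 4hn",
        ),
        flag_code=93,
        board="TAYSIDE",
        sample="unit",
    )
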