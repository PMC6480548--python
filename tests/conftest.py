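import pytest
from hypothesis import settings

from rems.org_model import OrgUnit, Quarter, validate_hierarchy

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_units(n_provinces=2, districts_per_province=2, facilities_per_district=2):
    units = [OrgUnit("NAT", "National", "national")]
    for p in range(1, n_provinces + 1):
        pid = f"P{p}"
        units.append(OrgUnit(pid, f"Province {p}", "provincial", "NAT"))
        for d in range(1, districts_per_province + 1):
            did = f"{pid}D{d}"
            units.append(OrgUnit(did, f"District {p}.{d}", "district", pid))
            for f in range(1, facilities_per_district + 1):
                units.append(
                    OrgUnit(f"{did}F{f}", f"Facility {p}.{d}.{f}", "facility", did,
                            facility_type="urban_health_centre")
                )
    return units


@pytest.fixture
def hierarchy():
    """1 national + 2 provinces + 4 districts + 8 facilities."""
    return validate_hierarchy(make_units())


@pytest.fixture
def q1():
    return Quarter(2016, 1)
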