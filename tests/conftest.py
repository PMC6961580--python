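import pytest

from koscan import SyntheticConfig, TargetSite, simulate_campaign
from koscan.io import sites_from_frame


def make_site(protospacer: str, pam: str = "AGG", label: str = "untested", **kw) -> TargetSite:
    defaults = dict(
        site_id=kw.pop("site_id", "s1"),
        gene_id=kw.pop("gene_id", "g1"),
        contig=kw.pop("contig", "chr1"),
        start=kw.pop("start", 0),
        end=kw.pop("end", 20),
        strand=kw.pop("strand", "+"),
    )
    return TargetSite(protospacer=protospacer, pam=pam, label=label, **defaults, **kw)


@pytest.fixture(scope="session")
def default_campaign():
    """One default-scale synthetic campaign, shared across tests."""
    return simulate_campaign(SyntheticConfig(rng_seed=7))


@pytest.fixture(scope="session")
def default_sites(default_campaign):
    return sites_from_frame(default_campaign.sites)
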