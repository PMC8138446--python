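import pytest

from liverheart.device import DeviceGeometry, TransportParams


@pytest.fixture(scope="session")
def geometry():
    return DeviceGeometry()


@pytest.fixture(scope="session")
def params():
    return TransportParams()
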