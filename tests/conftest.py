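import pytest

from coroflow import (
    BoundaryConditions,
    CrossSection,
    FluidProperties,
    LesionSpec,
    LongitudinalProfile,
    LossModelParams,
    SegmentSpec,
    Taper,
)


@pytest.fixture(scope="session")
def fluid() -> FluidProperties:
    return FluidProperties()


@pytest.fixture(scope="session")
def bc() -> BoundaryConditions:
    return BoundaryConditions()


@pytest.fixture(scope="session")
def params() -> LossModelParams:
    return LossModelParams()


def make_single(
    ds=0.7,
    length=5.0,
    cross=CrossSection.CONCENTRIC,
    profile=LongitudinalProfile.ROUNDED,
    taper=Taper.FOCAL,
    vessel_length=50.0,
    diameter=3.5,
) -> SegmentSpec:
    lesion = LesionSpec(
        ds_fraction=ds,
        length_mm=length,
        center_mm=vessel_length / 2.0,
        cross_section=cross,
        profile=profile,
        taper=taper,
    )
    return SegmentSpec(diameter_mm=diameter, length_mm=vessel_length, lesions=(lesion,))


def make_serial(
    count,
    ds=0.7,
    cross=CrossSection.CONCENTRIC,
    profile=LongitudinalProfile.ROUNDED,
    taper=Taper.FOCAL,
    vessel_length=100.0,
    gap=10.0,
    length=5.0,
) -> SegmentSpec:
    pitch = length + gap
    span = count * length + (count - 1) * gap
    first = (vessel_length - span + length) / 2.0
    lesions = tuple(
        LesionSpec(
            ds_fraction=ds,
            length_mm=length,
            center_mm=first + i * pitch,
            cross_section=cross,
            profile=profile,
            taper=taper,
        )
        for i in range(count)
    )
    return SegmentSpec(diameter_mm=3.5, length_mm=vessel_length, lesions=lesions)
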