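"""leafwater: leaf water content estimation from NIR hyperspectral images.

The package covers the full estimation workflow: ENVI cube I/O and
black/white calibration, leaf segmentation and mean-spectrum extraction,
chemometric preprocessing (SNV/MSC/SG/FD/min-max), the NISDI vegetation
index and exhaustive two-band index searches, CARS/SPA/UVE characteristic
wavelength selection, PLSR/MLR/RF/ANN regression, per-pixel water maps,
and a synthetic-data generator emulating drying-series leaf spectra.
"""

from importlib import resources as _resources

import pandas as _pd

from .grid import WavelengthGrid, default_grid
from .synth import (
    DryingRecord,
    PlantedSignal,
    SampleTable,
    SimConfig,
    VeinSpec,
    noiseless_spectrum,
    planted_nisdi_table,
    simulate_cube,
    simulate_drying_series,
    simulate_sample_table,
    simulate_spectrum,
    water_content,
)
from .cube import CalibrationFrames, HyperCube, calibrate, mean_spectrum, read_envi, segment_leaf, write_envi
from .prep import PrepMethod, compare_preprocessing, first_derivative, msc, normalize, savitzky_golay, snv
from .vindex import (
    PairIndexDef,
    PearsonResult,
    SearchResult,
    fit_index_model,
    nisdi,
    nisdi_table,
    pair_index,
    pearson,
    search_pairs,
    slope,
)
from .wavesel import SelectionResult, cars, spa, uve
from .regress import FitMetrics, RegressorSpec, evaluate, fit, kfold_cv, split
from .watermap import WaterMap, band_extractor, nisdi_extractor, predict_map, render_map
from .pipeline import FittedModel, PipelineConfig, StudyReport, cross_species_eval, rank_models, run

__version__ = "0.1.0"


def reference_model_metrics() -> "_pd.DataFrame":
    """Packaged reference table of published model-comparison metrics.

    Reported metric rows from the orchard drying study whose data structure
    the synthetic generator emulates; used to exercise the model-ranking
    rule against a known decision.
    """
    with _resources.files("leafwater.data").joinpath("reference_model_metrics.csv").open() as fh:
        return _pd.read_csv(fh)


def reference_selected_wavelengths() -> "_pd.DataFrame":
    """Packaged reference lists of published CARS/SPA/UVE wavelength picks."""
    with _resources.files("leafwater.data").joinpath("reference_selected_wavelengths.csv").open() as fh:
        return _pd.read_csv(fh)
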