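"""Bundled example data: the slope restoration grade standard and site data.

Fifteen indexes cover soil/water conservation (X1-X4), ecological effect
(X5-X8), substrate improvement (X9-X13) and landscape effect (X14-X15).
X6, X14 and X15 are qualitative-ordinal (fixed score g for grade g); the
rest are quantitative with half-open per-grade intervals.  Seven observed
slope sites, restored with seven different techniques, accompany it.
"""

from __future__ import annotations

from .grade_model import (
    EvaluationObject,
    GradeStandard,
    read_grade_standard,
    read_objects,
)

SLOPE_STANDARD_CSV = """\
index_id,name,kind,units,g1_lo,g1_hi,g2_lo,g2_hi,g3_lo,g3_hi,g4_lo,g4_hi,g5_lo,g5_hi
X1,Shearing strength of root-soil composite,quantitative,kPa,60,100,50,60,40,50,30,40,0,30
X2,Permeability,quantitative,mm h-1,30,40,20,30,10,20,5,10,0,5
X3,Soil erosion intensity,quantitative,g cm-3 a-1,0,5,5,15,15,25,25,35,35,45
X4,Root weight density,quantitative,kg m-3,3.5,4.5,2.5,3.5,1.5,2.5,0.5,1.5,0,0.5
X5,Vegetation coverage,quantitative,%,95,100,80,95,65,80,40,65,0,40
X6,Drought resistance of vegetation,qualitative,,1,,2,,3,,4,,5,
X7,Shannon-Wiener diversity index,quantitative,,3.0,3.5,2.5,3.0,2.0,2.5,1.5,2.0,0,1.5
X8,Pielou evenness index,quantitative,,1.0,1.2,0.8,1.0,0.6,0.8,0.4,0.6,0,0.4
X9,Organic matter,quantitative,g kg-1,30,40,20,30,10,20,5,10,0,5
X10,Available N,quantitative,mg kg-1,75,100,55,75,35,55,15,35,0,15
X11,Available P,quantitative,mg kg-1,30,40,20,30,10,20,5,10,0,5
X12,Available K,quantitative,mg kg-1,205,260,150,205,95,150,40,95,0,40
X13,Soil bulk density,quantitative,g cm-3,0,1.5,1.5,2.0,2.0,2.5,2.5,3.0,3.0,3.5
X14,Landscape coordination,qualitative,,1,,2,,3,,4,,5,
X15,Landscape capacity for visitors,qualitative,,1,,2,,3,,4,,5,
"""

SLOPE_SITES_CSV = """\
object_id,X1,X2,X3,X4,X5,X6,X7,X8,X9,X10,X11,X12,X13,X14,X15
1,39.82,17.15,33.87,2.27,30.51,5,1.46,0.65,9.87,38.58,8.67,100.25,2.6,4,3
2,50.26,15.25,34.26,2.58,86.36,3,2.86,0.95,16.54,50.21,18.52,130.25,2.06,2,2
3,54.36,21.36,28.35,2.32,90.28,2,2.36,0.83,22.57,58.57,20.06,132.52,2.12,2,3
4,58.79,29.86,11.56,3.08,97.27,2,2.83,0.95,29.85,68.56,26.58,186.52,1.32,1,2
5,35.28,19.82,22.58,2.39,35.06,5,1.55,0.7,10.24,35.67,13.65,90.42,2.65,3,4
6,49.85,14.26,29.65,2.06,48.36,4,1.64,0.68,12.34,45.62,10.15,88.67,2.31,3,3
7,75.66,26.87,17.26,3.26,95.55,2,2.68,0.86,26.57,63.27,23.56,176.53,1.38,1,2
"""


def load_slope_standard() -> GradeStandard:
    """The bundled 15-index slope restoration grade standard."""
    return read_grade_standard(SLOPE_STANDARD_CSV)


def load_slope_sites(standard: GradeStandard | None = None) -> list[EvaluationObject]:
    """The seven bundled slope sites, aligned to the bundled standard."""
    if standard is None:
        standard = load_slope_standard()
    return read_objects(SLOPE_SITES_CSV, standard)
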