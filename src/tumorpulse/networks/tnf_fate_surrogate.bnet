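# Surrogate TNF cell-fate network (6 nodes).
#
# A reduced stand-in for the published cell-fate signalling network, built to
# reproduce its qualitative TNF response under continuous-time stochastic
# (MaBoSS-style) semantics:
#   * TNF exposure opens a race between fast death commitment (Apoptosis /
#     NonACD, non-apoptotic death) and slower NFkB activation;
#   * NFkB blocks death commitment, and NFkB sustained together with TNF
#     slowly locks Survival -- the resistant state;
#   * Survival, Apoptosis and NonACD self-lock (down rate 0): committed cells
#     cannot go back;
#   * between pulses NFkB decays, so short pulses kill without inducing
#     resistance while prolonged exposure breeds Survival-locked cells.
# Rates are per minute and are this package's calibration, not literature
# values.

input TNF

readout Proliferation
readout Apoptosis
readout NonACD

NFkB          : TNF & !Apoptosis & !NonACD                      : 0.005 : 0.02
Survival      : (NFkB & TNF) | Survival                         : 0.001 : 0
Apoptosis     : (TNF & !NFkB & !Survival & !NonACD) | Apoptosis : 0.02  : 0
NonACD        : (TNF & !NFkB & !Survival & !Apoptosis) | NonACD : 0.02  : 0
Proliferation : !Apoptosis & !NonACD & (Survival | !TNF)        : 0.1   : 0.1
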