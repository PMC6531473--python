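# Synthetic example coefficients for the 29-gene matrisome signature.
#
# These are illustrative Cox log-hazard weights used by the synthetic
# pipeline and the documentation examples. They are NOT the pretrained
# clinical coefficients, which must be supplied by the user.
name: tmi-example
genes:
  COL11A1: {coefficient: 0.32}
  COL10A1: {coefficient: 0.27}
  COL6A6: {coefficient: -0.18}
  SPP1: {coefficient: 0.41}
  CTHRC1: {coefficient: 0.29}
  TNNC1: {coefficient: -0.12}
  ABI3BP: {coefficient: -0.21}
  PCOLCE2: {coefficient: -0.16}
  OGN: {coefficient: -0.24}
  MMP12: {coefficient: 0.35}
  MMP1: {coefficient: 0.30}
  ADAMTS5: {coefficient: -0.14}
  GREM1: {coefficient: 0.22}
  SFTPC: {coefficient: -0.33}
  SFTPA2: {coefficient: -0.28}
  SFTPD: {coefficient: -0.19}
  FCN3: {coefficient: -0.26}
  S100A2: {coefficient: 0.25}
  CXCL13: {coefficient: -0.11}
  WIF1: {coefficient: -0.17}
  CHRDL1: {coefficient: -0.15}
  CXCL2: {coefficient: 0.13}
  IL6: {coefficient: 0.20}
  HHIP: {coefficient: -0.22}
  S100A12: {coefficient: 0.18}
  LPL: {coefficient: -0.23}
  CPB2: {coefficient: -0.13}
  MAMDC2: {coefficient: -0.20}
  CD36: {coefficient: -0.25}
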