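# Bundled composition-scan experiments: each scan replaces a typical lipid
# by a ferroptosis-relevant one in 20% increments, 10 replicates per
# composition, 10 us production.
defaults:
  increment: 0.2
  n_replicates: 10
  n_per_leaflet: 128
  production_time_us: 10.0
experiments:
  - name: "SFA:PUFA"
    scans:
      - [DSPC, DOPC]
      - [DSPC, DLPC]
      - [DSPC, SOPC]
      - [DSPC, SLPC]
  - name: "PC:PE"
    scans:
      - [DSPC, DSPE]
      - [DOPC, DOPE]
      - [DLPC, DLPE]
  - name: "Lipid:ox-lipid"
    scans:
      - [DLPE, oxDLPE]
      - [SLPE, oxSLPE]
      - [DHPE, ox1DHPE]
      - [DHPE, ox2DHPE]
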