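# Default serum/plasma metabolite panel: 22 metabolites, 24 1H spin systems.
#
# delta    nominal chemical shift of the multiplet centre (ppm, glucose-
#          calibrated scale); used as the simulation ground-truth base and
#          as the centre of the training-time bootstrap seed window.
# window   coarse assignment search window (ppm); singlet coarse windows
#          are >= 0.01 ppm wide by construction.
# strategy pattern       J-coupling multiplet matching in `window`
#          correlation   singlet window narrowed by delta-correlation with
#                        the lactate/alanine methyl doublets
#          narrow_window fixed window small enough to need no narrowing
#          (acetone/acetate <= 0.006 ppm, formate <= 0.008 ppm)
# integration  which matched components are integrated (all / outer /
#          tallest / leftmost / rightmost); partial selections keep the
#          per-proton normalisation comparable via binomial-weight
#          pro-rating (3-hydroxybutyrate ships with `rightmost`, its
#          component furthest from the crowded 1.15-1.21 ppm region).
panel:
  - {metabolite: glucose,           system_id: glc-h1,    multiplicity: doublet, delta: 5.233, window: [5.15, 5.32],   j_hz: 3.8, n_protons: 1, strategy: pattern,       integration: all}
  - {metabolite: lactate,           system_id: lac-ch3,   multiplicity: doublet, delta: 1.330, window: [1.30, 1.36],   j_hz: 6.9, n_protons: 3, strategy: pattern,       integration: all}
  - {metabolite: alanine,           system_id: ala-ch3,   multiplicity: doublet, delta: 1.478, window: [1.45, 1.51],   j_hz: 7.2, n_protons: 3, strategy: pattern,       integration: all}
  - {metabolite: glycine,           system_id: gly-ch2,   multiplicity: singlet, delta: 3.561, window: [3.546, 3.576], n_protons: 2, strategy: correlation, correlation_refs: [lac-ch3, ala-ch3], integration: all}
  - {metabolite: creatine,          system_id: crt-ch3,   multiplicity: singlet, delta: 3.036, window: [3.020, 3.055], n_protons: 3, strategy: correlation, correlation_refs: [lac-ch3, ala-ch3], integration: all}
  - {metabolite: creatinine,        system_id: crn-ch3,   multiplicity: singlet, delta: 3.048, window: [3.030, 3.065], n_protons: 3, strategy: correlation, correlation_refs: [lac-ch3, ala-ch3], integration: all, crosscheck: crn-ch2}
  - {metabolite: creatinine,        system_id: crn-ch2,   multiplicity: singlet, delta: 4.058, window: [4.045, 4.075], n_protons: 2, strategy: correlation, correlation_refs: [lac-ch3, ala-ch3], integration: all, crosscheck: crn-ch3, primary: false}
  - {metabolite: choline,           system_id: cho-nme3,  multiplicity: singlet, delta: 3.205, window: [3.190, 3.220], n_protons: 9, strategy: correlation, correlation_refs: [lac-ch3, ala-ch3], integration: all}
  - {metabolite: dimethyl_sulfone,  system_id: dmso2-ch3, multiplicity: singlet, delta: 3.140, window: [3.125, 3.155], n_protons: 6, strategy: correlation, correlation_refs: [lac-ch3, ala-ch3], integration: all}
  - {metabolite: methionine,        system_id: met-sch3,  multiplicity: singlet, delta: 2.128, window: [2.110, 2.145], n_protons: 3, strategy: correlation, correlation_refs: [lac-ch3, ala-ch3], integration: all}
  # histidine's ring proton drifts the most with pH; its training seed
  # window must cover that drift or the harvest picks derivative side lobes
  - {metabolite: histidine,         system_id: his-h2,    multiplicity: singlet, delta: 7.770, window: [7.730, 7.810], n_protons: 1, strategy: correlation, correlation_refs: [lac-ch3, ala-ch3], integration: all, bootstrap_halfwidth: 0.012}
  - {metabolite: acetone,           system_id: act-ch3,   multiplicity: singlet, delta: 2.225, window: [2.2221, 2.2279], n_protons: 6, strategy: narrow_window, integration: all}
  - {metabolite: acetate,           system_id: ace-ch3,   multiplicity: singlet, delta: 1.918, window: [1.9151, 1.9209], n_protons: 3, strategy: narrow_window, integration: all}
  - {metabolite: formate,           system_id: for-ch,    multiplicity: singlet, delta: 8.455, window: [8.4511, 8.4589], n_protons: 1, strategy: narrow_window, integration: all}
  - {metabolite: ethanol,           system_id: eth-ch3,   multiplicity: triplet, delta: 1.190, window: [1.155, 1.215], j_hz: 7.1, n_protons: 3, strategy: pattern, integration: all}
  - {metabolite: 3-hydroxybutyrate, system_id: bhb-ch3,   multiplicity: doublet, delta: 1.236, window: [1.218, 1.254], j_hz: 6.3, n_protons: 3, strategy: pattern, integration: rightmost}
  - {metabolite: fructose,          system_id: fru-h,     multiplicity: doublet, delta: 4.110, window: [4.080, 4.140], j_hz: 3.9, n_protons: 1, strategy: pattern, integration: all}
  - {metabolite: tyrosine,          system_id: tyr-h35,   multiplicity: doublet, delta: 6.905, window: [6.870, 6.940], j_hz: 8.6, n_protons: 2, strategy: pattern, integration: all}
  - {metabolite: phenylalanine,     system_id: phe-h26,   multiplicity: doublet, delta: 7.370, window: [7.340, 7.400], j_hz: 7.5, n_protons: 2, strategy: pattern, integration: all}
  - {metabolite: glutamine,         system_id: gln-gch2,  multiplicity: triplet, delta: 2.440, window: [2.400, 2.480], j_hz: 7.6, n_protons: 2, strategy: pattern, integration: all}
  - {metabolite: valine,            system_id: val-ch3a,  multiplicity: doublet, delta: 0.984, window: [0.9735, 0.995], j_hz: 7.0, n_protons: 3, strategy: pattern, integration: all}
  - {metabolite: valine,            system_id: val-ch3b,  multiplicity: doublet, delta: 1.034, window: [1.020, 1.050], j_hz: 7.0, n_protons: 3, strategy: pattern, integration: all, primary: false}
  - {metabolite: leucine,           system_id: leu-ch3,   multiplicity: doublet, delta: 0.961, window: [0.951, 0.973], j_hz: 6.6, n_protons: 6, strategy: pattern, integration: all}
  # kept clear of the leucine doublet: a strong leucine tail can cancel a
  # weak isoleucine outer component by dispersion-derivative interference
  - {metabolite: isoleucine,        system_id: ile-dch3,  multiplicity: triplet, delta: 0.920, window: [0.895, 0.945], j_hz: 7.4, n_protons: 3, strategy: pattern, integration: all}
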