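# Base-case model configuration: five first-line strategies for metastatic
# renal-cell carcinoma, Chinese healthcare-system perspective, 2011 USD.
#
# Time unit throughout: 6-week model cycles (Weibull scale parameters are
# per cycle^shape; this is verified in the test suite against the source
# trials' published median survival times).
#
# Dose-intensity factors and the second-line intensity are calibration
# constants: they scale drug-acquisition costs so that the strategies'
# published lifetime stage costs are reproduced under this engine's
# occupancy convention.  docs/methods.md documents how they were derived;
# set them to 1.0 for fully mechanical bottom-up costing.

trials:
  # interferon-alfa arms of the four pivotal trials; weights are the
  # published interferon-arm enrolments
  negrier_1998:
    n_patients: 142
    pfs: {scale: 0.360096, se_scale: 0.0149185, shape: 0.7626, se_shape: 0.0237, correlation: -0.99954}
    os:  {scale: 0.064372, se_scale: 0.000922,  shape: 0.9871, se_shape: 0.0066, correlation: -0.99973}
  escudier_avoren:
    n_patients: 322
    pfs: {scale: 0.174161, se_scale: 0.004828,  shape: 1.024,  se_shape: 0.017,  correlation: -0.99962}
    os:  {scale: 0.043549, se_scale: 0.000682,  shape: 1.015,  se_shape: 0.007,  correlation: -0.99911}
  motzer_sunitinib:
    n_patients: 375
    pfs: {scale: 0.2447073, se_scale: 0.0078566, shape: 0.7914, se_shape: 0.0215, correlation: -0.99954}
    os:  {scale: 0.0476218, se_scale: 0.0012449, shape: 0.9666, se_shape: 0.0118, correlation: -0.999673}
  gore_re04:
    n_patients: 503
    pfs: {scale: 0.2288074, se_scale: 0.0094682, shape: 0.8361, se_shape: 0.0215, correlation: -0.99962}
    os:  {scale: 0.038574,  se_scale: 0.000943,  shape: 1.099,  se_shape: 0.011,  correlation: -0.99911}

strategies:
  interferon:
    hr_pfs: {mean: 1.0, ci_low: 1.0, ci_high: 1.0}
    hr_os:  {mean: 1.0, ci_low: 1.0, ci_high: 1.0}
    first_line: [interferon]
    dose_intensity: 1.961508
    sae: {neutropenia: 0.01, anaemia: 0.03, thrombocytopenia: 0.0099,
          nausea: 0.02, fatigue: 0.18, hypertension: 0.0066, proteinuria: 0.0}
  bevacizumab_interferon:
    hr_pfs: {mean: 0.63, ci_low: 0.52, ci_high: 0.75}
    hr_os:  {mean: 0.91, ci_low: 0.76, ci_high: 1.10}
    first_line: [bevacizumab, interferon]
    dose_intensity: 0.820556
    sae: {neutropenia: 0.04, anaemia: 0.03, thrombocytopenia: 0.02,
          nausea: 0.03, fatigue: 0.12, hypertension: 0.03, proteinuria: 0.07}
  sunitinib:
    hr_pfs: {mean: 0.42, ci_low: 0.32, ci_high: 0.54}
    hr_os:  {mean: 0.821, ci_low: 0.673, ci_high: 1.001}
    first_line: [sunitinib]
    dose_intensity: 0.611695
    sae: {neutropenia: 0.12, anaemia: 0.04, thrombocytopenia: 0.08,
          nausea: 0.04, fatigue: 0.07, hypertension: 0.08, proteinuria: 0.0}
  interleukin2:
    hr_pfs: {mean: 0.895, ci_low: 0.68, ci_high: 1.202}
    hr_os:  {mean: 1.083, ci_low: 0.718, ci_high: 1.394}
    first_line: [interleukin2]
    dose_intensity: 2.524268
    sae: {neutropenia: 0.05, anaemia: 0.02, thrombocytopenia: 0.0099,
          nausea: 0.05, fatigue: 0.25, hypertension: 0.04, proteinuria: 0.0}
  interleukin2_interferon:
    hr_pfs: {mean: 1.02, ci_low: 0.89, ci_high: 1.16}
    hr_os:  {mean: 1.05, ci_low: 0.90, ci_high: 1.21}
    first_line: [interleukin2, interferon]
    dose_intensity: 2.27834
    sae: {neutropenia: 0.05, anaemia: 0.02, thrombocytopenia: 0.0099,
          nausea: 0.05, fatigue: 0.25, hypertension: 0.04, proteinuria: 0.0}

prices:
  sunitinib_12_5mg:    {median: 71.5,  fixed: true, low: 71.5, high: 71.5}
  bevacizumab_100mg:   {median: 815.1, fixed: true, low: 815.1, high: 815.1}
  interferon_pack:     {median: 6.5,   low: 4.2,  high: 6.9}
  interleukin2_day:    {median: 13.4,  low: 12.0, high: 13.8}
  sorafenib_400mg:     {median: 64.5,  fixed: true, low: 64.5, high: 64.5}
  morphine_300mg:      {median: 1.4,   low: 1.3,  high: 1.6}
  drug_administration: {median: 18.5,  low: 16.6, high: 20.3}
  followup:            {median: 38.5,  low: 30.8, high: 53.8}
  sae_neutropenia:     {median: 461.5,  low: 415.4,  high: 507.7}
  sae_anaemia:         {median: 531.7,  low: 478.5,  high: 584.9}
  sae_thrombocytopenia: {median: 3551.7, low: 3196.5, high: 3906.9}
  sae_nausea:          {median: 44.3,   low: 39.9,   high: 48.7}
  sae_fatigue:         {median: 115.4,  low: 103.8,  high: 126.9}
  sae_hypertension:    {median: 12.9,   low: 11.6,   high: 14.2}
  # the published proteinuria range (5.8-7.1) is inconsistent with its own
  # unit cost; a 90-110% band around the unit cost is used instead
  sae_proteinuria:     {median: 115.4,  low: 103.9,  high: 126.9}

dosing:
  sunitinib:
    # 50 mg orally once daily, 4 weeks on / 2 weeks off
    price_item: sunitinib_12_5mg
    pack_size: 12.5
    route: oral
    steady: [{dose: 50, n: 28}]
  bevacizumab:
    # 10 mg/kg iv every 2 weeks; 65 kg typical patient, 100 mg vials discarded
    price_item: bevacizumab_100mg
    pack_size: 100
    route: iv
    steady: [{dose: 650, n: 3}]
  interferon:
    # sc 3x/week; titration 3 -> 6 -> 9 MU over the first three weeks,
    # 9 MU thereafter; priced per 3-MU dose-equivalent pack
    price_item: interferon_pack
    pack_size: 3
    route: sc
    first:  [{dose: 3, n: 3}, {dose: 6, n: 3}, {dose: 9, n: 12}]
    steady: [{dose: 9, n: 18}]
  interleukin2:
    # 18 MU x 1.72 m2 BSA iv daily for 5 days, every 3 weeks; priced per
    # day's infusion
    price_item: interleukin2_day
    pack_size: 30.96
    route: iv
    steady: [{dose: 30.96, n: 10}]
  sorafenib:
    # second line: 400 mg orally twice daily
    price_item: sorafenib_400mg
    pack_size: 400
    route: oral
    steady: [{dose: 400, n: 84}]
  morphine:
    # best supportive care: 300 mg twice daily
    price_item: morphine_300mg
    pack_size: 300
    route: oral
    steady: [{dose: 300, n: 84}]

second_line:
  # fractions of progressed patients; remainder receives best supportive
  # care.  "other targeted agents" (4.9%) are reassigned to sorafenib.
  shares:
    sunitinib: 0.142
    sorafenib: 0.171
    bevacizumab: 0.017
    cytokines: 0.335

utilities:
  # text-assigned values (the tabulated alternative is 0.65 / 0.47)
  pfs: 0.60
  ps: 0.45

engine:
  horizon: 87            # ceil(10 years / 6 weeks)
  discount_rate: 0.03
  state_model: partitioned
  half_cycle: false
  followup_in_ps: true
  spap_charge: flat
  second_line_intensity: 0.745459
  spap_second_line_paid_fraction: 0.409653
  wtp: 13290.0           # 3 x mainland per-capita GDP ($4,430)

sensitivity:
  n_iterations: 1000
  sd_fraction: 0.10
  sae_range_fraction: 0.10
  discount_low: 0.0
  discount_high: 0.05
  seed: 20110101

regions:
  # 2010 per-capita GDP (USD); acceptability thresholds are 3x these
  mainland_china: 4430
  shanghai: 10828
  tianjin: 10400
  beijing: 10378
  jiangsu: 7682
  zhejiang: 7390
  inner_mongolia: 6969
  guangdong: 6440
  liaoning: 6172
  shandong: 6078
  fujian: 5748
  jilin: 4614
  hebei: 4152
  hubei: 4079
  chongqing: 4043
  shaanxi: 3966
  heilongjiang: 3946
  ningxia: 3853
  shanxi: 3759
  xinjiang: 3670
  henan: 3605
  hunan: 3576
  qinghai: 3545
  hainan: 3496
  jiangxi: 3127
  sichuan: 3104
  guangxi: 3050
  anhui: 3045
  tibet: 2497
  gansu: 2379
  yunnan: 2320
  guizhou: 1953
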