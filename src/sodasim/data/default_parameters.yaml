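# Default model inputs for the California soda-tax cost-effectiveness model.
# All costs in 2022 USD per person per year; utilities are EQ-5D weights;
# transition probabilities are annual. "uncertainty: pm25" entries derive
# their bounds as +/-25% of the mean unless explicit bounds are given
# (utility intervals are clipped at 1).

run:
  n_individuals: 20000
  horizon_years: 20
  cycle_length: 1.0
  discount_rate: 0.03
  rescale_factor: 1462.36      # 29,247,121 California adults / 20,000 simulated
  wtp: 100000
  calories_per_gram_sugar: 4.0
  kcal_per_pound: 3500.0
  lb_per_kg: 2.20462
  days_per_year: 365
  natural_gain_range: [0.45, 0.91]
  tax_weight_effect: -0.56
  annual_revenue: 862722888
  admin_cost_fraction: 0.01
  seed: 20150101

parameters:
  weight_change_soda_tax:
    {mean: -0.56, low: -1.93, high: 0.77, uncertainty: ci95, family: normal}
  tax_revenue_per_year:
    {mean: 862722888, uncertainty: pm25, family: gamma}
  admin_cost_per_year:
    {mean: 8627229, uncertainty: pm25, family: gamma}

costs:
  normal:     {mean: 0, uncertainty: fixed}
  overweight: {mean: 1320, low: 1069, high: 1607, uncertainty: ci95, family: gamma}
  obesity:    {mean: 3955, low: 3519, high: 4363, uncertainty: ci95, family: gamma}
  diabetes:   {mean: 21218, uncertainty: pm25, family: gamma}
  stroke:     {mean: 103425, uncertainty: pm25, family: gamma}
  poststroke: {mean: 38159, uncertainty: pm25, family: gamma}
  mi:         {mean: 138603, uncertainty: pm25, family: gamma}
  postmi:     {mean: 4675, uncertainty: pm25, family: gamma}
  esrd:       {mean: 176647, uncertainty: pm25, family: gamma}

utilities:
  normal:            {mean: 1.0, low: 0.75, high: 1.0, uncertainty: pm25, family: beta}
  overweight:        {mean: 0.876, low: 0.657, high: 1.0, uncertainty: pm25, family: beta}
  obesity:           {mean: 0.850, low: 0.637, high: 1.0, uncertainty: pm25, family: beta}
  diabetes:          {mean: 0.785, low: 0.681, high: 0.889, uncertainty: ci95, family: beta}
  stroke_poststroke: {mean: 0.621, low: 0.459, high: 0.784, uncertainty: ci95, family: beta}
  mi_postmi:         {mean: 0.730, low: 0.614, high: 0.847, uncertainty: ci95, family: beta}
  esrd:              {mean: 0.61, low: 0.51, high: 0.71, uncertainty: ci95, family: beta}
  death:             {mean: 0, uncertainty: fixed}

transitions:
  normal:
    diabetes: {mean: 0.0069, low: 0.0058, high: 0.0083, uncertainty: ci95}
    stroke:   {mean: 0.0028, low: 0.0025, high: 0.0032, uncertainty: ci95}
    mi:       {mean: 0.0028, low: 0.0025, high: 0.0033, uncertainty: ci95}
    esrd:     {mean: 0.0004, uncertainty: pm25}
    death:    {mean: 0.0090, uncertainty: pm25}
  overweight:
    diabetes: {mean: 0.0088, low: 0.0084, high: 0.0092, uncertainty: ci95}
    stroke:   {mean: 0.0029, low: 0.0027, high: 0.0033, uncertainty: ci95}
    mi:       {mean: 0.0033, low: 0.0028, high: 0.0039, uncertainty: ci95}
    esrd:     {mean: 0.0005, low: 0.0005, high: 0.0006, uncertainty: ci95}
    death:    {mean: 0.0087, low: 0.0087, high: 0.0087, uncertainty: ci95}
  obesity:
    diabetes: {mean: 0.0135, low: 0.0119, high: 0.0154, uncertainty: ci95}
    stroke:   {mean: 0.0035, low: 0.0032, high: 0.0039, uncertainty: ci95}
    mi:       {mean: 0.0044, low: 0.0034, high: 0.0055, uncertainty: ci95}
    esrd:     {mean: 0.0007, low: 0.0006, high: 0.0008, uncertainty: ci95}
    death:    {mean: 0.0118, low: 0.0117, high: 0.0119, uncertainty: ci95}
  diabetes:
    stroke:   {mean: 0.0042, low: 0.0032, high: 0.0057, uncertainty: ci95}
    mi:       {mean: 0.0051, low: 0.0038, high: 0.0067, uncertainty: ci95}
    esrd:     {mean: 0.0023, low: 0.0022, high: 0.0024, uncertainty: ci95}
    death:    {mean: 0.0128, low: 0.0120, high: 0.0137, uncertainty: ci95}
  stroke:
    mi:       {mean: 0.03, low: 0.01, high: 0.05, uncertainty: ci95}
    death:    {mean: 0.17, uncertainty: pm25}
  mi:
    stroke:   {mean: 0.081, uncertainty: pm25}
    death:    {mean: 0.22, uncertainty: pm25}
  esrd:
    stroke:   {mean: 0.0172, low: 0.0146, high: 0.0200, uncertainty: ci95}
    mi:       {mean: 0.0040, low: 0.0032, high: 0.0050, uncertainty: ci95}
    death:    {mean: 0.034, uncertainty: pm25}
  poststroke:
    mi:       {mean: 0.0167, low: 0.0136, high: 0.0198, uncertainty: ci95}
    death:    {mean: 0.0173, low: 0.0119, high: 0.0235, uncertainty: ci95}
  postmi:
    stroke:   {mean: 0.0087, low: 0.0083, high: 0.0092, uncertainty: ci95}
    death:    {mean: 0.21, uncertainty: pm25}
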