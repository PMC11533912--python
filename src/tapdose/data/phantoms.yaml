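# Reference phantoms: organ masses (kg) and organ absorbed-dose limits (Gy).
# Human masses follow ICRP-89-style reference adults; mouse masses are
# typical laboratory values for ~25 g animals.  All values overridable via
# user-supplied phantom files.
mouse_male:
  species: mouse
  sex: male
  body_mass_kg: 0.025
  organs:
    blood:           {mass_kg: 0.00170}
    kidneys:         {mass_kg: 0.00040, dose_limit_Gy: 23}
    liver:           {mass_kg: 0.00130, dose_limit_Gy: 30}
    pancreas:        {mass_kg: 0.00025}
    spleen:          {mass_kg: 0.00010, dose_limit_Gy: 26}
    lungs:           {mass_kg: 0.00015, dose_limit_Gy: 65}
    heart:           {mass_kg: 0.00013, dose_limit_Gy: 45}
    stomach:         {mass_kg: 0.00020, dose_limit_Gy: 45}
    urinary_bladder: {mass_kg: 0.00003, dose_limit_Gy: 20}
    red_marrow:      {mass_kg: 0.00022, dose_limit_Gy: 2}
    tumor:           {mass_kg: 0.00030}
mouse_female:
  species: mouse
  sex: female
  body_mass_kg: 0.022
  organs:
    blood:           {mass_kg: 0.00150}
    kidneys:         {mass_kg: 0.00035, dose_limit_Gy: 23}
    liver:           {mass_kg: 0.00115, dose_limit_Gy: 30}
    pancreas:        {mass_kg: 0.00022}
    spleen:          {mass_kg: 0.00009, dose_limit_Gy: 26}
    lungs:           {mass_kg: 0.00014, dose_limit_Gy: 65}
    heart:           {mass_kg: 0.00012, dose_limit_Gy: 45}
    stomach:         {mass_kg: 0.00018, dose_limit_Gy: 45}
    urinary_bladder: {mass_kg: 0.00003, dose_limit_Gy: 20}
    red_marrow:      {mass_kg: 0.00020, dose_limit_Gy: 2}
    tumor:           {mass_kg: 0.00030}
human_female:
  species: human
  sex: female
  body_mass_kg: 60.0
  organs:
    blood:           {mass_kg: 4.100}
    kidneys:         {mass_kg: 0.275, dose_limit_Gy: 23}
    liver:           {mass_kg: 1.400, dose_limit_Gy: 30}
    pancreas:        {mass_kg: 0.120}
    spleen:          {mass_kg: 0.130, dose_limit_Gy: 26}
    lungs:           {mass_kg: 0.950, dose_limit_Gy: 65}
    heart:           {mass_kg: 0.250, dose_limit_Gy: 45}
    stomach:         {mass_kg: 0.140, dose_limit_Gy: 45}
    urinary_bladder: {mass_kg: 0.040, dose_limit_Gy: 20}
    red_marrow:      {mass_kg: 0.900, dose_limit_Gy: 2}
human_male:
  species: human
  sex: male
  body_mass_kg: 73.0
  organs:
    blood:           {mass_kg: 5.300}
    kidneys:         {mass_kg: 0.310, dose_limit_Gy: 23}
    liver:           {mass_kg: 1.800, dose_limit_Gy: 30}
    pancreas:        {mass_kg: 0.140}
    spleen:          {mass_kg: 0.150, dose_limit_Gy: 26}
    lungs:           {mass_kg: 1.200, dose_limit_Gy: 65}
    heart:           {mass_kg: 0.330, dose_limit_Gy: 45}
    stomach:         {mass_kg: 0.150, dose_limit_Gy: 45}
    urinary_bladder: {mass_kg: 0.050, dose_limit_Gy: 20}
    red_marrow:      {mass_kg: 1.170, dose_limit_Gy: 2}
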