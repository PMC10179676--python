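name,compartment,units,direction_policy,source_group,include_in_model
male_age,male_demographic,years,upper,pregnancy,true
ejaculate_volume,ejaculate,mL,none,pregnancy,false
ejaculate_concentration,ejaculate,10^6 sperm/mL,lower,pregnancy,true
ejaculate_total_count,ejaculate,10^6 sperm,lower,pregnancy,true
ejaculate_progressive_motility,ejaculate,%,lower,pregnancy,true
ejaculate_immotile,ejaculate,%,upper,pregnancy,true
ejaculate_total_motile,ejaculate,10^6 sperm,lower,pregnancy,true
ejaculate_morphology,ejaculate,%,lower,pregnancy,true
ejaculate_alkaline_comet,ejaculate,%,upper,pregnancy,true
ejaculate_neutral_comet,ejaculate,%,upper,pregnancy,true
swimup_concentration,swim_up,10^6 sperm/mL,none,pregnancy,false
swimup_total_count,swim_up,10^6 sperm,none,pregnancy,false
swimup_progressive_motility,swim_up,%,lower,pregnancy,true
swimup_immotile,swim_up,%,upper,pregnancy,true
swimup_total_motile,swim_up,10^6 sperm,none,pregnancy,false
swimup_alkaline_comet,swim_up,%,upper,pregnancy,true
swimup_neutral_comet,swim_up,%,upper,pregnancy,true
female_age,female,years,upper,no_pregnancy,true
female_bmi,female,kg/m^2,upper,no_pregnancy,true
infertility_duration,female,months,upper,no_pregnancy,true
fsh,female,mUI/mL,upper,pregnancy,true
lh,female,mUI/mL,upper,no_pregnancy,true
estradiol,female,pg/mL,lower,no_pregnancy,true
prolactin,female,ng/mL,none,pregnancy,false
antral_follicle_count,female,count,lower,no_pregnancy,true
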