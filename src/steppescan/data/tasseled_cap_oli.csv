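# Tasseled-cap coefficients for Landsat-8 OLI at-sensor reflectance
# (Baig, Zhang, Shuai & Tong 2014, Remote Sensing Letters 5:423-431).
# Rows: components; columns: the six reflective OLI bands 2-7.
# The coastal band does not enter the transform (coefficient 0).
component,coastal,blue,green,red,nir,swir1,swir2
brightness,0.0,0.3029,0.2786,0.4733,0.5599,0.5080,0.1872
greenness,0.0,-0.2941,-0.2430,-0.5424,0.7276,0.0713,-0.1608
wetness,0.0,0.1511,0.1973,0.3283,0.3407,-0.7117,-0.4559
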