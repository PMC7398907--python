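<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2" level="3" version="1" fbc:required="false">
  <model id="TOY1" name="TOY-1" fbc:strict="false">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
      <compartment id="e" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="glc_e" name="D-glucose" compartment="e" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="C6H12O6"/>
      <species id="glc_c" name="D-glucose" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="C6H12O6"/>
      <species id="nh4_e" name="ammonium" compartment="e" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="1" fbc:chemicalFormula="NH4"/>
      <species id="nh4_c" name="ammonium" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="1" fbc:chemicalFormula="NH4"/>
      <species id="biomass_c" name="biomass" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="true" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="EX_glc_lb" value="-1000" constant="true"/>
      <parameter id="EX_glc_ub" value="1000" constant="true"/>
      <parameter id="EX_nh4_lb" value="-1000" constant="true"/>
      <parameter id="EX_nh4_ub" value="1000" constant="true"/>
      <parameter id="T_glc_lb" value="0" constant="true"/>
      <parameter id="T_glc_ub" value="1000" constant="true"/>
      <parameter id="T_nh4_lb" value="0" constant="true"/>
      <parameter id="T_nh4_ub" value="1000" constant="true"/>
      <parameter id="BIOMASS_lb" value="0" constant="true"/>
      <parameter id="BIOMASS_ub" value="1000" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="EX_glc" name="glucose exchange" reversible="true" fast="false" fbc:lowerFluxBound="EX_glc_lb" fbc:upperFluxBound="EX_glc_ub">
        <listOfReactants>
          <speciesReference species="glc_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="EX_nh4" name="ammonium exchange" reversible="true" fast="false" fbc:lowerFluxBound="EX_nh4_lb" fbc:upperFluxBound="EX_nh4_ub">
        <listOfReactants>
          <speciesReference species="nh4_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="T_glc" name="glucose transport" reversible="false" fast="false" fbc:lowerFluxBound="T_glc_lb" fbc:upperFluxBound="T_glc_ub">
        <listOfReactants>
          <speciesReference species="glc_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="glc_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="T_nh4" name="ammonium transport" reversible="false" fast="false" fbc:lowerFluxBound="T_nh4_lb" fbc:upperFluxBound="T_nh4_ub">
        <listOfReactants>
          <speciesReference species="nh4_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="nh4_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="BIOMASS" name="biomass" reversible="false" fast="false" fbc:lowerFluxBound="BIOMASS_lb" fbc:upperFluxBound="BIOMASS_ub">
        <listOfReactants>
          <speciesReference species="glc_c" stoichiometry="1" constant="true"/>
          <speciesReference species="nh4_c" stoichiometry="0.5" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="biomass_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="BIOMASS" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
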