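import pytest

import gsda
from gsda.fixtures import (
    FixtureConfig,
    isoenzyme_feedback_model,
    linear_pathway,
    toy_moiety_model,
)


@pytest.fixture(scope="session")
def chain_model():
    return linear_pathway()


@pytest.fixture(scope="session")
def chain_fb_product():
    return linear_pathway(FixtureConfig(feedback="product_on_first"))


@pytest.fixture(scope="session")
def chain_fb_internal():
    return linear_pathway(FixtureConfig(feedback="internal_on_first"))


@pytest.fixture(scope="session")
def moiety_model():
    return toy_moiety_model()


@pytest.fixture(scope="session")
def iso_model():
    return isoenzyme_feedback_model()


@pytest.fixture(scope="session")
def all_models(chain_model, chain_fb_product, chain_fb_internal, moiety_model,
               iso_model):
    return [chain_model, chain_fb_product, chain_fb_internal, moiety_model,
            iso_model]


@pytest.fixture(scope="session")
def chain_ss(chain_model):
    return gsda.steady_state(chain_model, raise_on_failure=True)


SBML_CHAIN = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="sbml_chain">
  <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
  <listOfSpecies>
   <species id="X0" compartment="cell" initialConcentration="1" boundaryCondition="true"/>
   <species id="S" compartment="cell" initialConcentration="0.5"/>
   <species id="P" compartment="cell" initialConcentration="0.5"/>
   <species id="X1" compartment="cell" initialConcentration="0.0001" boundaryCondition="true"/>
  </listOfSpecies>
  <listOfParameters>
   <parameter id="k1" value="10"/><parameter id="k2" value="5"/>
   <parameter id="k3" value="10"/><parameter id="q" value="10"/>
  </listOfParameters>
  <listOfReactions>
   <reaction id="v1">
    <listOfReactants><speciesReference species="X0"/></listOfReactants>
    <listOfProducts><speciesReference species="S"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
     <apply><times/><ci>k1</ci>
      <apply><minus/><ci>X0</ci><apply><divide/><ci>S</ci><ci>q</ci></apply></apply>
     </apply></math></kineticLaw>
   </reaction>
   <reaction id="v2">
    <listOfReactants><speciesReference species="S"/></listOfReactants>
    <listOfProducts><speciesReference species="P"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
     <apply><times/><ci>k2</ci>
      <apply><minus/><ci>S</ci><apply><divide/><ci>P</ci><ci>q</ci></apply></apply>
     </apply></math>
     <listOfParameters><parameter id="k2" value="5"/></listOfParameters>
    </kineticLaw>
   </reaction>
   <reaction id="v3">
    <listOfReactants><speciesReference species="P"/></listOfReactants>
    <listOfProducts><speciesReference species="X1"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
     <apply><times/><ci>k3</ci>
      <apply><minus/><ci>P</ci><apply><divide/><ci>X1</ci><ci>q</ci></apply></apply>
     </apply></math></kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


@pytest.fixture(scope="session")
def sbml_chain_text():
    return SBML_CHAIN


@pytest.fixture(scope="session")
def sbml_chain_model():
    return gsda.read_sbml(SBML_CHAIN)
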